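"""Deterministic synthetic test files and named corruption operators.

This module is the package's test and acceptance surface: it writes small,
structurally valid files in every supported format (bit-identical for a given
spec) and can inject exactly one named defect per file.  Each operator maps
to the check expected to catch it — that operator→check table is the ground
truth for the soundness/completeness matrix.

Record content is biologically arbitrary (seeded random IUPAC strings);
structural validity, not realism, is the goal.  Every fixture is written with
a matching ``.sha512`` sidecar and, for indexed container formats, a minimal
index companion, so that a corruption-free fixture passes the complete
pipeline in thorough + strict mode.
"""

from __future__ import annotations

import gzip
import json
import random
import struct
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

from . import bgzf
from .integrity import compute_digest
from .model import BAM, CRAM, FASTQ, SAM, VCF, ZIP, CheckId
from .validators.alignment import CRAM_EOF

NO_CORRUPTION = "NONE"

#: Operator → expected failing check, per (format, compressed) applicability.
#: Operators absent for a pair are refused by make_fixture.
_GRAMMAR = CheckId.FORMAT_OK
_COMP = CheckId.COMPRESSION_OK
_SUM = CheckId.CHECKSUM_OK
_IDX = CheckId.INDEX_PRESENT

_TABLE: dict[tuple[str, bool], dict[str, CheckId]] = {
    (FASTQ, False): {
        "LENGTH_MISMATCH": _GRAMMAR,
        "DROP_QUALITY_LINE": _GRAMMAR,
        "BAD_HEADER_CHAR": _GRAMMAR,
        "STALE_CHECKSUM": _SUM,
    },
    (FASTQ, True): {
        "LENGTH_MISMATCH": _GRAMMAR,
        "DROP_QUALITY_LINE": _GRAMMAR,
        "BAD_HEADER_CHAR": _GRAMMAR,
        "TRUNCATE_TAIL": _COMP,
        "BYTE_FLIP": _COMP,
        "STALE_CHECKSUM": _SUM,
    },
    (SAM, False): {
        "LENGTH_MISMATCH": _GRAMMAR,
        "FIELD_COUNT_MISMATCH": _GRAMMAR,
        "ZERO_READS": _GRAMMAR,
        "STALE_CHECKSUM": _SUM,
    },
    (BAM, True): {
        "BAD_MAGIC": _GRAMMAR,
        "ZERO_READS": _GRAMMAR,
        "TRUNCATE_TAIL": _COMP,
        "STRIP_EOF_BLOCK": _COMP,
        "BYTE_FLIP": _COMP,
        "DROP_INDEX": _IDX,
        "STALE_CHECKSUM": _SUM,
    },
    (CRAM, False): {
        "BAD_MAGIC": _GRAMMAR,
        "STRIP_EOF_BLOCK": _GRAMMAR,
        "TRUNCATE_TAIL": _GRAMMAR,
        "DROP_INDEX": _IDX,
        "STALE_CHECKSUM": _SUM,
    },
    (VCF, False): {
        "DROP_FILEFORMAT": _GRAMMAR,
        "FIELD_COUNT_MISMATCH": _GRAMMAR,
        "BAD_POS": _GRAMMAR,
        "BAD_REF_CHAR": _GRAMMAR,
        "STALE_CHECKSUM": _SUM,
    },
    (VCF, True): {
        "DROP_FILEFORMAT": _GRAMMAR,
        "FIELD_COUNT_MISMATCH": _GRAMMAR,
        "BAD_POS": _GRAMMAR,
        "BAD_REF_CHAR": _GRAMMAR,
        "TRUNCATE_TAIL": _COMP,
        "STRIP_EOF_BLOCK": _COMP,
        "BYTE_FLIP": _COMP,
        "DROP_INDEX": _IDX,
        "STALE_CHECKSUM": _SUM,
    },
    (ZIP, False): {
        "TRUNCATE_TAIL": _GRAMMAR,
        "BYTE_FLIP": _GRAMMAR,
        "STALE_CHECKSUM": _SUM,
    },
}

_EXTENSIONS = {
    (FASTQ, False): ".fastq",
    (FASTQ, True): ".fastq.gz",
    (SAM, False): ".sam",
    (BAM, True): ".bam",
    (CRAM, False): ".cram",
    (VCF, False): ".vcf",
    (VCF, True): ".vcf.gz",
    (ZIP, False): ".zip",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic synthetic file."""

    format: str
    seed: int
    n_records: int = 10
    corruption: str = NO_CORRUPTION
    compressed: bool = False

    def normalized(self) -> "FixtureSpec":
        # BAM is inherently BGZF; CRAM/SAM/ZIP have no compressed variant.
        compressed = self.compressed
        if self.format == BAM:
            compressed = True
        elif self.format in (SAM, CRAM, ZIP):
            compressed = False
        if compressed != self.compressed:
            return FixtureSpec(
                self.format, self.seed, self.n_records, self.corruption, compressed
            )
        return self


def applicable_corruptions(fmt: str, compressed: bool = False) -> dict[str, CheckId]:
    """Operators valid for a format variant, mapped to their target check."""
    key = (fmt, True if fmt == BAM else (False if fmt in (SAM, CRAM, ZIP) else compressed))
    if key not in _TABLE:
        raise ValueError(f"unsupported fixture format: {fmt!r}")
    return dict(_TABLE[key])


def expected_failure(spec: FixtureSpec) -> CheckId | None:
    """The check a corrupted fixture must fail; None for a valid fixture."""
    spec = spec.normalized()
    if spec.corruption == NO_CORRUPTION:
        return None
    return applicable_corruptions(spec.format, spec.compressed)[spec.corruption]


def all_variants() -> list[tuple[str, bool]]:
    return list(_TABLE)


def _rng(spec: FixtureSpec, salt: str = "") -> random.Random:
    return random.Random(f"{spec.format}:{spec.seed}:{spec.n_records}:{salt}")


# ---------------------------------------------------------------------------
# valid content builders


def _fastq_lines(spec: FixtureSpec) -> list[str]:
    rng = _rng(spec)
    lines = []
    for i in range(spec.n_records):
        length = rng.randint(30, 60)
        seq = "".join(rng.choice("ACGTACGTACGTACGTN") for _ in range(length))
        qual = "".join(chr(rng.randint(33, 74)) for _ in range(length))
        lines += [f"@read{i:04d}", seq, "+", qual]
    return lines


def _alignment_content(spec: FixtureSpec):
    """Shared header/reference/record material for SAM and BAM."""
    rng = _rng(spec)
    refs = [("chr1", 1000), ("chr2", 800)]
    header_lines = ["@HD\tVN:1.6"] + [
        f"@SQ\tSN:{name}\tLN:{length}" for name, length in refs
    ]
    records = []
    for i in range(spec.n_records):
        refid = rng.randrange(len(refs))
        length = rng.randint(30, 60)
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        qual = "".join(chr(rng.randint(33, 73)) for _ in range(length))
        pos = rng.randint(1, refs[refid][1] - length)
        mapq = rng.randint(20, 60)
        records.append((f"read{i:04d}", 0, refid, pos, mapq, seq, qual))
    return header_lines, refs, records


def _sam_lines(spec: FixtureSpec) -> list[str]:
    header_lines, refs, records = _alignment_content(spec)
    lines = list(header_lines)
    for qname, flag, refid, pos, mapq, seq, qual in records:
        lines.append(
            "\t".join(
                [
                    qname,
                    str(flag),
                    refs[refid][0],
                    str(pos),
                    str(mapq),
                    f"{len(seq)}M",
                    "*",
                    "0",
                    "0",
                    seq,
                    qual,
                ]
            )
        )
    return lines


_NIB = {ch: idx for idx, ch in enumerate("=ACMGRSVTWYHKDBN")}
_BAM_FIXED = struct.Struct("<iiBBHHHiiii")


def _encode_bam_record(qname, flag, refid, pos, mapq, seq, qual) -> bytes:
    name = qname.encode("ascii") + b"\x00"
    body = _BAM_FIXED.pack(
        refid, pos - 1, len(name), mapq, 0, 1, flag, len(seq), -1, -1, 0
    )
    body += name
    body += struct.pack("<I", (len(seq) << 4) | 0)  # single M cigar op
    nibbles = bytearray()
    for i in range(0, len(seq), 2):
        hi = _NIB[seq[i]]
        lo = _NIB[seq[i + 1]] if i + 1 < len(seq) else 0
        nibbles.append((hi << 4) | lo)
    body += bytes(nibbles)
    body += bytes(ord(c) - 33 for c in qual)
    return struct.pack("<i", len(body)) + body


def _bam_payload(spec: FixtureSpec, n_records: int | None = None) -> bytes:
    header_lines, refs, records = _alignment_content(spec)
    if n_records is not None:
        records = records[:n_records]
    text = ("\n".join(header_lines) + "\n").encode("ascii")
    out = bytearray(b"BAM\x01")
    out += struct.pack("<i", len(text)) + text
    out += struct.pack("<i", len(refs))
    for name, length in refs:
        nb = name.encode("ascii") + b"\x00"
        out += struct.pack("<i", len(nb)) + nb + struct.pack("<i", length)
    for record in records:
        out += _encode_bam_record(*record)
    return bytes(out)


def _vcf_lines(spec: FixtureSpec) -> list[str]:
    rng = _rng(spec)
    n_samples = rng.randint(0, 3)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=seqcheck-fixture",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "##FILTER=<ID=PASS,Description=\"All filters passed\">",
    ]
    columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if n_samples:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        columns += ["FORMAT"] + [f"sample{j}" for j in range(n_samples)]
    lines.append("\t".join(columns))
    pos = 0
    for _ in range(spec.n_records):
        pos += rng.randint(1, 5000)
        chrom = rng.choice(["chr1", "chr2", "chr3"])
        ref = rng.choice(["A", "C", "G", "T", "AT", "GC"])
        alt = rng.choice(["A", "C", "G", "T", "<DEL>", "*"])
        fields = [
            chrom,
            str(pos),
            ".",
            ref,
            alt,
            f"{rng.randint(10, 99)}",
            "PASS",
            f"DP={rng.randint(1, 200)}",
        ]
        if n_samples:
            fields.append("GT:DP")
            fields += [
                f"{rng.choice(['0/0', '0/1', '1/1'])}:{rng.randint(1, 99)}"
                for _ in range(n_samples)
            ]
        lines.append("\t".join(fields))
    return lines


def _zip_bytes(spec: FixtureSpec, out_path: Path) -> None:
    rng = _rng(spec)
    with zipfile.ZipFile(out_path, "w") as archive:
        for i in range(max(1, spec.n_records)):
            info = zipfile.ZipInfo(f"entry_{i:03d}.txt", date_time=(1980, 1, 1, 0, 0, 0))
            text = "".join(rng.choice("abcdefghij \n") for _ in range(120))
            archive.writestr(info, text, compress_type=zipfile.ZIP_STORED)


def _cram_bytes(spec: FixtureSpec) -> bytes:
    rng = _rng(spec)
    filler = bytes(rng.randrange(256) for _ in range(128 + 4 * spec.n_records))
    return b"CRAM" + bytes([3, 0]) + filler + CRAM_EOF


# ---------------------------------------------------------------------------
# corruption operators


def _corrupt_lines(
    spec: FixtureSpec, lines: list[str]
) -> tuple[list[str], dict]:
    """Text-level operators; returns modified lines + defect location."""
    op = spec.corruption
    rng = _rng(spec, "corrupt")
    defect: dict = {"operator": op}
    if spec.format == FASTQ:
        k = rng.randrange(spec.n_records)
        if op == "LENGTH_MISMATCH":
            idx = 4 * k + 3
            lines[idx] = lines[idx][:-1]
            defect["line"] = idx + 1
        elif op == "DROP_QUALITY_LINE":
            idx = 4 * k + 3
            del lines[idx]
            defect["line"] = idx + 1
        elif op == "BAD_HEADER_CHAR":
            idx = 4 * k
            lines[idx] = "#" + lines[idx][1:]
            defect["line"] = idx + 1
        return lines, defect
    if spec.format == SAM:
        n_header = sum(1 for ln in lines if ln.startswith("@"))
        k = rng.randrange(spec.n_records) if spec.n_records else 0
        idx = n_header + k
        if op == "LENGTH_MISMATCH":
            fields = lines[idx].split("\t")
            fields[10] = fields[10][:-1]
            lines[idx] = "\t".join(fields)
            defect["line"] = idx + 1
        elif op == "FIELD_COUNT_MISMATCH":
            fields = lines[idx].split("\t")
            lines[idx] = "\t".join(fields[:-1])
            defect["line"] = idx + 1
        return lines, defect
    if spec.format == VCF:
        first_record = next(
            i for i, ln in enumerate(lines) if not ln.startswith("#")
        )
        k = rng.randrange(spec.n_records)
        idx = first_record + k
        fields = lines[idx].split("\t")
        if op == "DROP_FILEFORMAT":
            del lines[0]
            defect["line"] = 1
            return lines, defect
        if op == "FIELD_COUNT_MISMATCH":
            lines[idx] = "\t".join(fields[:-1])
        elif op == "BAD_POS":
            fields[1] = fields[1] + "x"
            lines[idx] = "\t".join(fields)
        elif op == "BAD_REF_CHAR":
            fields[3] = "AXG"
            lines[idx] = "\t".join(fields)
        defect["line"] = idx + 1
        return lines, defect
    return lines, defect


def _truncate(data: bytes) -> bytes:
    amount = 100 if len(data) > 140 else max(30, len(data) // 3)
    return data[:-amount]


def _flip_gzip_payload(data: bytes, rng: random.Random) -> tuple[bytes, int]:
    offset = rng.randrange(10, len(data))  # past the 10-byte gzip header
    flipped = bytearray(data)
    flipped[offset] ^= 0xFF
    return bytes(flipped), offset


def _flip_bgzf_payload(data: bytes, rng: random.Random) -> tuple[bytes, int]:
    bsize = struct.unpack_from("<H", data, 16)[0]
    cdata_start, cdata_end = 18, bsize + 1 - 8
    offset = rng.randrange(cdata_start, cdata_end)
    flipped = bytearray(data)
    flipped[offset] ^= 0xFF
    return bytes(flipped), offset


def _flip_zip_entry(path: Path, rng: random.Random) -> int:
    with zipfile.ZipFile(path) as archive:
        info = archive.infolist()[0]
    data = bytearray(path.read_bytes())
    name_len, extra_len = struct.unpack_from("<HH", data, info.header_offset + 26)
    data_start = info.header_offset + 30 + name_len + extra_len
    offset = data_start + rng.randrange(max(1, info.compress_size))
    data[offset] ^= 0xFF
    path.write_bytes(bytes(data))
    return offset


# ---------------------------------------------------------------------------
# assembly


def _write_index(path: Path, spec: FixtureSpec) -> Path | None:
    if spec.format == BAM:
        index = path.with_name(path.name + ".bai")
        n_ref = 2
        index.write_bytes(
            b"BAI\x01" + struct.pack("<i", n_ref) + struct.pack("<ii", 0, 0) * n_ref
        )
        return index
    if spec.format == CRAM:
        index = path.with_name(path.name + ".crai")
        index.write_bytes(gzip.compress(b"0\t0\t0\t0\t0\t0\n", mtime=0))
        return index
    if spec.format == VCF and spec.compressed:
        index = path.with_name(path.name + ".tbi")
        index.write_bytes(bgzf.compress(b"TBI\x01" + b"\x00" * 28))
        return index
    return None


def _build_bytes(spec: FixtureSpec, out_path: Path, stale_pass: bool = False):
    """Write the (possibly corrupted) fixture bytes; returns defect info.

    ``stale_pass`` rebuilds the *valid* content with perturbed record material
    (used for the second write of STALE_CHECKSUM).
    """
    op = spec.corruption
    content_spec = spec
    if stale_pass:
        content_spec = FixtureSpec(
            spec.format, spec.seed + 99991, spec.n_records, NO_CORRUPTION, spec.compressed
        )
        op = NO_CORRUPTION
    defect: dict = {"operator": spec.corruption}

    text_formats = {FASTQ: _fastq_lines, SAM: _sam_lines, VCF: _vcf_lines}
    if spec.format in text_formats:
        lines = text_formats[spec.format](content_spec)
        if op in (
            "LENGTH_MISMATCH",
            "DROP_QUALITY_LINE",
            "BAD_HEADER_CHAR",
            "FIELD_COUNT_MISMATCH",
            "BAD_POS",
            "BAD_REF_CHAR",
            "DROP_FILEFORMAT",
        ):
            lines, defect = _corrupt_lines(spec, lines)
        if op == "ZERO_READS":  # SAM: header only
            lines = [ln for ln in lines if ln.startswith("@")]
        payload = ("\n".join(lines) + "\n").encode("ascii") if lines else b""
        if spec.compressed:
            if spec.format == VCF:
                data = bgzf.compress(payload)
            else:
                data = gzip.compress(payload, mtime=0)
        else:
            data = payload
    elif spec.format == BAM:
        n = 0 if op == "ZERO_READS" else None
        payload = _bam_payload(content_spec, n_records=n)
        if op == "BAD_MAGIC":
            payload = b"XXXX" + payload[4:]
        data = bgzf.compress(payload)
    elif spec.format == CRAM:
        data = _cram_bytes(content_spec)
        if op == "BAD_MAGIC":
            data = b"XXXX" + data[4:]
    elif spec.format == ZIP:
        _zip_bytes(content_spec, out_path)
        data = None
    else:
        raise ValueError(f"unsupported fixture format: {spec.format!r}")

    rng = _rng(spec, "bytes")
    if data is not None:
        if op == "TRUNCATE_TAIL":
            data = _truncate(data)
        elif op == "STRIP_EOF_BLOCK":
            marker = CRAM_EOF if spec.format == CRAM else bgzf.BGZF_EOF
            assert data.endswith(marker)
            data = data[: -len(marker)]
        elif op == "BYTE_FLIP":
            if spec.format == VCF or spec.format == BAM:
                data, offset = _flip_bgzf_payload(data, rng)
            else:
                data, offset = _flip_gzip_payload(data, rng)
            defect["offset"] = offset
        out_path.write_bytes(data)
    else:  # ZIP was written directly
        if op == "TRUNCATE_TAIL":
            out_path.write_bytes(_truncate(out_path.read_bytes()))
        elif op == "BYTE_FLIP":
            defect["offset"] = _flip_zip_entry(out_path, rng)
    return defect


def make_fixture(spec: FixtureSpec, out_dir: Path | str) -> Path:
    """Write the fixture described by ``spec`` into ``out_dir``.

    Writes the data file, a matching ``.sha512`` sidecar (stale for
    STALE_CHECKSUM), an index companion where the format has one (omitted for
    DROP_INDEX) and a ``.manifest.json`` recording the recipe and the injected
    defect.  Same spec ⇒ byte-identical output.
    """
    spec = spec.normalized()
    if spec.n_records < 1 and spec.corruption != "ZERO_READS":
        raise ValueError("n_records must be >= 1")
    if spec.corruption != NO_CORRUPTION:
        table = applicable_corruptions(spec.format, spec.compressed)
        if spec.corruption not in table:
            raise ValueError(
                f"corruption {spec.corruption} not applicable to "
                f"{spec.format} (compressed={spec.compressed})"
            )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = _EXTENSIONS[(spec.format, spec.compressed)]
    name = f"{spec.format}_s{spec.seed}_n{spec.n_records}_{spec.corruption.lower()}{ext}"
    path = out_dir / name

    defect = _build_bytes(spec, path)
    sidecar = path.with_name(path.name + ".sha512")
    sidecar.write_text(f"{compute_digest(path, 'sha512')}  {path.name}\n")
    if spec.corruption == "STALE_CHECKSUM":
        # Regenerate valid content after the sidecar was written: the file is
        # sound, the sidecar is stale.
        _build_bytes(spec, path, stale_pass=True)

    index_path = None
    if spec.corruption != "DROP_INDEX":
        index_path = _write_index(path, spec)

    target = expected_failure(spec)
    manifest = {
        "spec": asdict(spec),
        "path": path.name,
        "expected_failure": target.value if target else None,
        "defect": defect,
        "sidecar": sidecar.name,
        "index": index_path.name if index_path else None,
    }
    path.with_name(path.name + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return path
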