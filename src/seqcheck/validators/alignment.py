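"""SAM / BAM / CRAM validation and index companionship.

SAM is validated as text against the v1 layout (header record types, @SQ
name/length rules, 11 mandatory fields with range checks).  BAM is validated
at the container level: BGZF payload must open with the ``BAM\\x01`` magic,
carry a well-formed text header and reference directory, and contain at least
one decodable alignment record; thorough mode walks every record checking
that block sizes chain exactly to the end of the stream.  CRAM validation is
deliberately container-level only (magic + version + the fixed 38-byte v3 EOF
container); full CRAM codec parsing is out of proportion to an input/output
sanity check.
"""

from __future__ import annotations

import gzip
import struct
from pathlib import Path

from .. import bgzf
from ..model import (
    BAM,
    CRAM,
    SAM,
    AlignmentHeaderInfo,
    CheckId,
    CheckResult,
    CompanionSet,
    FileCategory,
    Severity,
)
from . import _io

_QUICK_RECORDS = 4

#: Fixed EOF container terminating a CRAM v3 file.
CRAM_EOF = bytes.fromhex(
    "0f000000ffffffff0fe0454f4600000000010005bdd94f0001000606010001000100ee63014b"
)

_HEADER_TYPES = {"@HD", "@SQ", "@RG", "@PG", "@CO"}


def _parse_header_lines(
    lines: list[str], info: AlignmentHeaderInfo
) -> tuple[int, str] | None:
    """Validate SAM header lines (shared by SAM text and BAM text header).

    Returns ``(1-based line number, message)`` for the first defect.
    """
    seen_sn: set[str] = set()
    for idx, line in enumerate(lines, start=1):
        fields = line.split("\t")
        tag = fields[0]
        if tag == "@CO":
            continue
        if tag not in _HEADER_TYPES:
            return (idx, f"unrecognized header record type {tag!r}")
        pairs = {}
        for field in fields[1:]:
            if ":" not in field:
                return (idx, f"malformed {tag} field {field!r}")
            key, _, value = field.partition(":")
            pairs[key] = value
        if tag == "@HD":
            if idx != 1:
                return (idx, "@HD must be the first line")
            if "VN" not in pairs:
                return (idx, "@HD missing VN")
            info.has_hd = True
            info.hd_version = pairs["VN"]
        elif tag == "@SQ":
            if "SN" not in pairs or "LN" not in pairs:
                return (idx, "@SQ missing SN or LN")
            name = pairs["SN"]
            if name in seen_sn:
                return (idx, f"duplicate @SQ SN {name!r}")
            seen_sn.add(name)
            try:
                length = int(pairs["LN"])
            except ValueError:
                return (idx, f"@SQ LN not an integer: {pairs['LN']!r}")
            if length < 1:
                return (idx, f"@SQ LN must be positive, got {length}")
            info.reference_sequences.append((name, length))
    return None


def _check_alignment_fields(
    fields: list[str], lineno: int, ref_names: set[str]
) -> tuple[int, str] | None:
    if len(fields) < 11:
        return (lineno, f"alignment line has {len(fields)} fields, expected ≥11")
    try:
        flag = int(fields[1])
    except ValueError:
        return (lineno, f"FLAG not an integer: {fields[1]!r}")
    if not 0 <= flag <= 65535:
        return (lineno, f"FLAG out of range: {flag}")
    try:
        pos = int(fields[3])
    except ValueError:
        return (lineno, f"POS not an integer: {fields[3]!r}")
    if not 0 <= pos <= 2**31 - 1:
        return (lineno, f"POS out of range: {pos}")
    try:
        mapq = int(fields[4])
    except ValueError:
        return (lineno, f"MAPQ not an integer: {fields[4]!r}")
    if not 0 <= mapq <= 255:
        return (lineno, f"MAPQ out of range: {mapq}")
    seq, qual = fields[9], fields[10]
    if seq != "*" and qual != "*" and len(seq) != len(qual):
        return (
            lineno,
            f"SEQ length {len(seq)} ≠ QUAL length {len(qual)}",
        )
    rname = fields[2]
    if ref_names and rname != "*" and rname not in ref_names:
        return (lineno, f"RNAME {rname!r} not declared in any @SQ")
    return None


def validate_sam(
    path: Path | str, thorough: bool = False, category: FileCategory | None = None
) -> tuple[CheckResult, AlignmentHeaderInfo]:
    from ..detect import detect_file_type

    category = category or detect_file_type(path)
    info = AlignmentHeaderInfo()
    header_lines: list[str] = []
    first_error: tuple[int, str] | None = None
    n_records = 0
    header_done = False
    ref_names: set[str] = set()

    try:
        for lineno, line in enumerate(_io.iter_lines(path, category), start=1):
            if line.startswith("@"):
                if header_done:
                    first_error = first_error or (
                        lineno,
                        "header line after alignment records",
                    )
                    break
                header_lines.append(line)
                continue
            if not header_done:
                header_done = True
                err = _parse_header_lines(header_lines, info)
                if err is not None:
                    first_error = err
                    break
                ref_names = {name for name, _ in info.reference_sequences}
            n_records += 1
            if thorough or n_records <= _QUICK_RECORDS:
                err = _check_alignment_fields(line.split("\t"), lineno, ref_names)
                if err is not None:
                    first_error = first_error or err
                    break
            elif not thorough and n_records > _QUICK_RECORDS:
                # Quick mode: presence established, grammar sampled.
                pass
    except _io.STREAM_ERRORS as exc:
        return (
            CheckResult(CheckId.FORMAT_OK, False, f"read failed: {exc}"),
            info,
        )

    if first_error is None and not header_done:
        # Header-only file: still validate the header before complaining.
        err = _parse_header_lines(header_lines, info)
        if err is not None:
            first_error = err
    if first_error is None and n_records == 0:
        first_error = (len(header_lines) + 1, "no reads: at least one alignment line required")
    info.read_seen = n_records > 0

    if first_error is not None:
        lineno, message = first_error
        return (
            CheckResult(CheckId.FORMAT_OK, False, f"{message} at line {lineno}"),
            info,
        )
    return CheckResult(CheckId.FORMAT_OK, True), info


_BAM_RECORD_FIXED = struct.Struct("<iiBBHHHiiii")


def validate_bam(
    path: Path | str, thorough: bool = False
) -> tuple[CheckResult, AlignmentHeaderInfo]:
    info = AlignmentHeaderInfo()

    def fail(detail: str) -> tuple[CheckResult, AlignmentHeaderInfo]:
        return CheckResult(CheckId.FORMAT_OK, False, detail), info

    raw = Path(path).read_bytes()
    try:
        data = bgzf.decompress(raw)
    except bgzf.BgzfError as exc:
        return fail(f"BGZF container unreadable: {exc}")

    if data[:4] != b"BAM\x01":
        return fail("bad BAM magic: decompressed stream does not start with BAM\\x01")
    off = 4
    if len(data) < off + 4:
        return fail(f"truncated BAM header at offset {off}")
    (l_text,) = struct.unpack_from("<i", data, off)
    off += 4
    if l_text < 0 or off + l_text > len(data):
        return fail(f"header text length {l_text} overruns data at offset {off}")
    text = data[off : off + l_text].rstrip(b"\x00").decode("latin-1")
    off += l_text
    header_lines = [ln for ln in text.split("\n") if ln]
    err = _parse_header_lines(header_lines, info)
    if err is not None:
        return fail(f"{err[1]} at header line {err[0]}")

    if len(data) < off + 4:
        return fail(f"truncated reference directory at offset {off}")
    (n_ref,) = struct.unpack_from("<i", data, off)
    off += 4
    if n_ref < 0:
        return fail(f"negative n_ref at offset {off - 4}")
    binary_refs: list[tuple[str, int]] = []
    for i in range(n_ref):
        if len(data) < off + 4:
            return fail(f"truncated reference record {i} at offset {off}")
        (l_name,) = struct.unpack_from("<i", data, off)
        off += 4
        if l_name < 1 or len(data) < off + l_name + 4:
            return fail(f"bad reference name length {l_name} at offset {off}")
        name_bytes = data[off : off + l_name]
        if name_bytes[-1] != 0:
            return fail(f"reference name not NUL-terminated at offset {off}")
        off += l_name
        (l_ref,) = struct.unpack_from("<i", data, off)
        off += 4
        if l_ref < 1:
            return fail(f"non-positive reference length at offset {off - 4}")
        binary_refs.append((name_bytes[:-1].decode("latin-1"), l_ref))

    if info.reference_sequences and len(info.reference_sequences) != n_ref:
        return fail(
            f"n_ref {n_ref} does not match {len(info.reference_sequences)} @SQ lines"
        )
    if not info.reference_sequences:
        info.reference_sequences = binary_refs

    n_records = 0
    while off < len(data):
        if len(data) < off + 4:
            return fail(f"record overruns data at offset {off}")
        (block_size,) = struct.unpack_from("<i", data, off)
        if block_size < _BAM_RECORD_FIXED.size or off + 4 + block_size > len(data):
            return fail(f"record overruns data at offset {off}")
        refid, pos, l_read_name = struct.unpack_from("<iiB", data, off + 4)
        if not -1 <= refid < n_ref:
            return fail(f"refID {refid} out of range at offset {off}")
        if pos < -1:
            return fail(f"pos {pos} out of range at offset {off}")
        if l_read_name < 1:
            return fail(f"empty read name at offset {off}")
        off += 4 + block_size
        n_records += 1
        if not thorough and n_records >= _QUICK_RECORDS:
            break

    info.read_seen = n_records > 0
    if n_records == 0:
        return fail("no reads: BAM contains zero alignment records")
    return CheckResult(CheckId.FORMAT_OK, True), info


def validate_cram(path: Path | str) -> CheckResult:
    data = Path(path).read_bytes()
    if data[:4] != b"CRAM":
        return CheckResult(CheckId.FORMAT_OK, False, "bad CRAM magic")
    if len(data) < 6 or not 1 <= data[4] <= 3:
        return CheckResult(
            CheckId.FORMAT_OK, False, f"implausible CRAM version byte {data[4:5].hex()}"
        )
    if not data.endswith(CRAM_EOF):
        return CheckResult(CheckId.FORMAT_OK, False, "missing EOF container")
    return CheckResult(CheckId.FORMAT_OK, True)


def _index_magic_ok(index_path: Path) -> tuple[bool, str]:
    head = index_path.read_bytes()[:4]
    name = index_path.name.lower()
    if name.endswith(".bai"):
        if head != b"BAI\x01":
            return False, f"bad BAI magic in {index_path.name}"
        return True, ""
    if name.endswith((".csi", ".tbi")):
        raw = index_path.read_bytes()
        expected = b"CSI\x01" if name.endswith(".csi") else b"TBI\x01"
        try:
            inner = bgzf.decompress(raw) if raw[:2] == bgzf.GZIP_MAGIC else raw
        except bgzf.BgzfError:
            try:
                inner = gzip.decompress(raw)
            except OSError:
                return False, f"unreadable index container {index_path.name}"
        if inner[:4] != expected:
            return False, f"bad {expected[:3].decode()} magic in {index_path.name}"
        return True, ""
    if name.endswith(".crai"):
        if head[:2] != bgzf.GZIP_MAGIC:
            return False, f"CRAI index not gzip-compressed: {index_path.name}"
        return True, ""
    return True, ""


def check_alignment_index(
    path: Path | str,
    companions: CompanionSet,
    thorough: bool = False,
    strict: bool = False,
) -> CheckResult:
    """Confirm an index companion accompanies an indexed container format.

    A missing index is reported at WARNING severity by default (the file
    itself may be perfectly sound); strict mode upgrades it to a verdict
    failure.
    """
    severity = Severity.ERROR if strict else Severity.WARNING
    if not companions.index_files:
        return CheckResult(
            CheckId.INDEX_PRESENT, False, "no index found", severity
        )
    if thorough:
        for index_path in companions.index_files:
            ok, detail = _index_magic_ok(Path(index_path))
            if not ok:
                return CheckResult(CheckId.INDEX_PRESENT, False, detail, severity)
    return CheckResult(CheckId.INDEX_PRESENT, True)


def run(
    path: Path,
    category: FileCategory,
    companions: CompanionSet,
    thorough: bool,
    strict: bool,
) -> list[CheckResult]:
    if category.format == SAM:
        result, _ = validate_sam(path, thorough=thorough, category=category)
        return [result]
    if category.format == BAM:
        result, _ = validate_bam(path, thorough=thorough)
    elif category.format == CRAM:
        result = validate_cram(path)
    else:  # pragma: no cover - registry misconfiguration
        raise ValueError(f"alignment validator cannot handle {category.format}")
    results = [result]
    if result.passed:
        results.append(
            check_alignment_index(path, companions, thorough=thorough, strict=strict)
        )
    return results
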