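"""VCF grammar validation (plain or BGZF/gzip compressed).

Checks are deliberately grammar-level: header shape (``##fileformat`` first,
meta lines carrying ``=``, exactly one ``#CHROM`` line with the eight fixed
columns and optional FORMAT + samples) and per-record field syntax.  Semantic
cross-checks (ALT ≠ REF, contigs declared in the header, INFO/FORMAT typing)
are intentionally out of scope — this is an input/output sanity gate, not a
call-set curator.
"""

from __future__ import annotations

import re
from pathlib import Path

from ..model import (
    CheckId,
    CheckResult,
    CompanionSet,
    Compression,
    FileCategory,
    VcfHeaderInfo,
)
from . import _io
from .alignment import check_alignment_index

_QUICK_RECORDS = 4

_FIXED_COLUMNS = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
_FILEFORMAT_RE = re.compile(r"^##fileformat=VCFv(\d+(?:\.\d+)?)$")
_SEQ_ALLELE_RE = re.compile(r"^[ACGTNacgtn]+$")
_SYMBOLIC_RE = re.compile(r"^<[^<>]+>$")
_INFO_TOKEN_RE = re.compile(r"^[^;=\s]+(=[^;\s]*)?$")


def _check_alt(alt: str) -> bool:
    if alt == ".":
        return True
    for allele in alt.split(","):
        if not allele:
            return False
        if _SEQ_ALLELE_RE.match(allele):
            continue
        if _SYMBOLIC_RE.match(allele):
            continue
        if "[" in allele or "]" in allele:
            continue
        if allele == "*":
            continue
        return False
    return True


def _check_record(
    fields: list[str], lineno: int, info: VcfHeaderInfo
) -> tuple[int, str] | None:
    if len(fields) != info.column_count:
        return (
            lineno,
            f"field count {len(fields)} ≠ header column count {info.column_count}",
        )
    chrom, pos, _id, ref, alt, qual, filt, inf = fields[:8]
    if not chrom or any(ch.isspace() for ch in chrom):
        return (lineno, f"bad CHROM {chrom!r}")
    if not pos.isdigit() or int(pos) < 1:
        return (lineno, f"POS not a positive integer: {pos!r}")
    if not _SEQ_ALLELE_RE.match(ref):
        return (lineno, f"REF not a nucleotide string: {ref!r}")
    if not _check_alt(alt):
        return (lineno, f"malformed ALT {alt!r}")
    if qual != ".":
        try:
            value = float(qual)
        except ValueError:
            return (lineno, f"QUAL not a number: {qual!r}")
        if value < 0:
            return (lineno, f"QUAL negative: {qual!r}")
    if not filt:
        return (lineno, "empty FILTER")
    if inf != ".":
        for token in inf.split(";"):
            if not _INFO_TOKEN_RE.match(token):
                return (lineno, f"malformed INFO token {token!r}")
    if info.sample_names:
        fmt = fields[8]
        fmt_keys = fmt.split(":")
        if "GT" in fmt_keys and fmt_keys[0] != "GT":
            return (lineno, "FORMAT contains GT but not first")
        for sample_field in fields[9:]:
            if len(sample_field.split(":")) > len(fmt_keys):
                return (lineno, f"sample field {sample_field!r} longer than FORMAT")
    return None


def validate_vcf(
    path: Path | str,
    category: FileCategory | None = None,
    thorough: bool = False,
    strict: bool = False,
) -> tuple[CheckResult, VcfHeaderInfo]:
    from ..detect import detect_file_type

    category = category or detect_file_type(path)
    info = VcfHeaderInfo()
    first_error: tuple[int, str] | None = None
    chrom_seen = False
    note = ""

    try:
        for lineno, line in enumerate(_io.iter_lines(path, category), start=1):
            if lineno == 1:
                match = _FILEFORMAT_RE.match(line)
                if match is None:
                    first_error = (1, "missing fileformat declaration")
                    break
                info.fileformat = match.group(1)
                if not info.fileformat.startswith("4"):
                    note = f"unusual VCF version {info.fileformat}"
                continue
            if line.startswith("##"):
                if chrom_seen or info.record_count:
                    first_error = (lineno, "meta line after the #CHROM line")
                    break
                if "=" not in line:
                    first_error = (lineno, "meta line without '='")
                    break
                continue
            if line.startswith("#"):
                if chrom_seen:
                    first_error = (lineno, "duplicate #CHROM line")
                    break
                cols = line.split("\t")
                if cols[: len(_FIXED_COLUMNS)] != _FIXED_COLUMNS:
                    first_error = (lineno, "malformed #CHROM column header")
                    break
                if len(cols) == len(_FIXED_COLUMNS):
                    pass
                elif len(cols) >= 10 and cols[8] == "FORMAT":
                    info.sample_names = cols[9:]
                    if len(set(info.sample_names)) != len(info.sample_names):
                        first_error = (lineno, "duplicate sample names")
                        break
                else:
                    first_error = (lineno, "sample columns require a FORMAT column")
                    break
                info.column_count = len(cols)
                chrom_seen = True
                continue
            # data record
            if not chrom_seen:
                first_error = (lineno, "variant record before #CHROM line")
                break
            info.record_count += 1
            if thorough or info.record_count <= _QUICK_RECORDS:
                err = _check_record(line.split("\t"), lineno, info)
                if err is not None:
                    first_error = err
                    break
    except _io.STREAM_ERRORS as exc:
        return (CheckResult(CheckId.FORMAT_OK, False, f"read failed: {exc}"), info)

    if first_error is None and not chrom_seen:
        first_error = (1, "missing #CHROM column header")
    if first_error is None and info.record_count == 0:
        if strict:
            first_error = (1, "no variant records (strict mode)")
        else:
            note = (note + "; " if note else "") + "header-only VCF, no records"

    if first_error is not None:
        lineno, message = first_error
        return (
            CheckResult(CheckId.FORMAT_OK, False, f"{message} at line {lineno}"),
            info,
        )
    return CheckResult(CheckId.FORMAT_OK, True, note), info


def run(
    path: Path,
    category: FileCategory,
    companions: CompanionSet,
    thorough: bool,
    strict: bool,
) -> list[CheckResult]:
    result, _ = validate_vcf(path, category, thorough=thorough, strict=strict)
    results = [result]
    if result.passed and category.compression in (Compression.GZIP, Compression.BGZF):
        results.append(
            check_alignment_index(path, companions, thorough=thorough, strict=strict)
        )
    return results
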