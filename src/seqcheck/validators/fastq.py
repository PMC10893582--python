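"""FASTQ grammar validation (plain or gzip).

A FASTQ file is a sequence of 4-line records:

1. ``@`` + non-empty identifier,
2. non-empty sequence over the IUPAC nucleotide alphabet,
3. ``+`` optionally repeating the identifier (must match when present —
   this strict reading catches shuffled/interleaved corruption),
4. quality string, same length as the sequence, characters in ASCII 33–126.

The total line count must be a multiple of 4 and at least one record is
required.  Quick mode validates only the first 4 records plus the line-count
rule; thorough mode validates every record.  CRLF endings are tolerated and
the final newline is optional.
"""

from __future__ import annotations

from pathlib import Path

from ..model import CheckId, CheckResult, CompanionSet, FastqStats, FileCategory
from . import _io

_IUPAC = set("ACGTURYSWKMBDHVN" + "ACGTURYSWKMBDHVN".lower())

_QUICK_RECORDS = 4


def validate_fastq(
    path: Path | str, category: FileCategory, thorough: bool = False
) -> tuple[CheckResult, FastqStats]:
    stats = FastqStats()
    record: list[str] = []
    line_count = 0
    first_error: tuple[int, str] | None = None

    try:
        for line in _io.iter_lines(path, category):
            line_count += 1
            record.append(line)
            if len(record) < 4:
                continue
            record_no = line_count // 4  # 1-based
            base = line_count - 3  # line number of the header line
            if first_error is None and (thorough or record_no <= _QUICK_RECORDS):
                first_error = _check_record(record, base)
            if first_error is None:
                stats.record_count += 1
            record = []
    except _io.STREAM_ERRORS as exc:
        return (
            CheckResult(
                CheckId.FORMAT_OK,
                False,
                f"decompression failed after line {line_count}: {exc}",
            ),
            stats,
        )

    if first_error is None and line_count % 4 != 0:
        first_error = (line_count, f"line count {line_count} not a multiple of 4")
    if first_error is None and line_count == 0:
        first_error = (1, "no records: file has no FASTQ content")

    if first_error is not None:
        lineno, message = first_error
        stats.first_bad_line = lineno
        return (
            CheckResult(CheckId.FORMAT_OK, False, f"{message} at line {lineno}"),
            stats,
        )
    return CheckResult(CheckId.FORMAT_OK, True), stats


def _check_record(record: list[str], base: int) -> tuple[int, str] | None:
    header, seq, plus, qual = record
    if not header.startswith("@") or len(header) < 2:
        return (base, "record header must start with '@' and a non-empty identifier")
    if not seq:
        return (base + 1, "empty sequence line")
    for ch in seq:
        if ch not in _IUPAC:
            return (base + 1, f"non-IUPAC sequence character {ch!r}")
    if not plus.startswith("+"):
        return (base + 2, "separator line must start with '+'")
    if len(plus) > 1 and plus[1:] != header[1:]:
        return (base + 2, "separator identifier does not repeat the header")
    if len(qual) != len(seq):
        return (
            base + 3,
            f"quality length {len(qual)} ≠ sequence length {len(seq)}",
        )
    for ch in qual:
        if not 33 <= ord(ch) <= 126:
            return (base + 3, f"quality character out of ASCII 33-126: {ch!r}")
    return None


def run(
    path: Path,
    category: FileCategory,
    companions: CompanionSet,
    thorough: bool,
    strict: bool,
) -> list[CheckResult]:
    result, _ = validate_fastq(path, category, thorough=thorough)
    return [result]
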