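"""ZIP archive validation against the PKZIP layout.

Quick mode locates the End-Of-Central-Directory record in the final
65 KiB + 22 bytes and cross-checks its entry count against the enumerable
central directory.  Thorough mode additionally decompresses every entry and
compares its CRC32 to the central-directory value, failing on the first
mismatch with the entry name.  ZIP64 archives are accepted in quick mode
(EOCD64 locator found) but thorough CRC walking of ZIP64 is unsupported and
flagged as such.
"""

from __future__ import annotations

import struct
import zlib
from pathlib import Path

from ..model import CheckId, CheckResult, CompanionSet, FileCategory, Severity

EOCD_SIG = b"PK\x05\x06"
CEN_SIG = b"PK\x01\x02"
LOC_SIG = b"PK\x03\x04"
EOCD64_LOCATOR_SIG = b"PK\x06\x07"

_EOCD = struct.Struct("<4sHHHHIIH")
_CEN = struct.Struct("<4sHHHHHHIIIHHHHHII")
_LOC = struct.Struct("<4sHHHHHIIIHH")

_SENTINEL16 = 0xFFFF
_SENTINEL32 = 0xFFFFFFFF


def _find_eocd(data: bytes) -> int | None:
    window_start = max(0, len(data) - (65536 + 22))
    idx = data.rfind(EOCD_SIG, window_start)
    return None if idx < 0 else idx


def validate_zip(path: Path | str, thorough: bool = False) -> CheckResult:
    data = Path(path).read_bytes()

    def fail(detail: str, severity: Severity = Severity.ERROR) -> CheckResult:
        return CheckResult(CheckId.FORMAT_OK, False, detail, severity)

    eocd_at = _find_eocd(data)
    if eocd_at is None or eocd_at + _EOCD.size > len(data):
        return fail("cannot locate end of central directory")
    (_, _, _, _, n_total, cd_size, cd_offset, _) = _EOCD.unpack_from(data, eocd_at)

    zip64 = n_total == _SENTINEL16 or cd_offset == _SENTINEL32 or cd_size == _SENTINEL32
    if zip64:
        if data.rfind(EOCD64_LOCATOR_SIG, 0, eocd_at) < 0:
            return fail("ZIP64 sentinel values but no EOCD64 locator")
        if thorough:
            return fail("ZIP64 archive: thorough CRC walk unsupported", Severity.WARNING)
        return CheckResult(CheckId.FORMAT_OK, True, "ZIP64 archive (quick check only)")

    entries = []
    off = cd_offset
    while off < eocd_at and data[off : off + 4] == CEN_SIG:
        if off + _CEN.size > len(data):
            return fail(f"truncated central directory entry at offset {off}")
        cen = _CEN.unpack_from(data, off)
        (_, _, _, flags, method, _, _, crc, csize, usize,
         name_len, extra_len, comment_len, _, _, _, header_offset) = cen
        name = data[off + _CEN.size : off + _CEN.size + name_len].decode(
            "cp437", errors="replace"
        )
        entries.append((name, flags, method, crc, csize, usize, header_offset))
        off += _CEN.size + name_len + extra_len + comment_len
    if len(entries) != n_total:
        return fail(
            f"central directory lists {len(entries)} entries, EOCD claims {n_total}"
        )

    if not thorough:
        return CheckResult(CheckId.FORMAT_OK, True)

    for name, flags, method, crc, csize, usize, header_offset in entries:
        if flags & 0x1:
            return fail(f"encrypted entry unsupported: {name}")
        if header_offset + _LOC.size > len(data) or data[
            header_offset : header_offset + 4
        ] != LOC_SIG:
            return fail(f"bad local header for entry {name}")
        loc = _LOC.unpack_from(data, header_offset)
        loc_name_len, loc_extra_len = loc[9], loc[10]
        data_start = header_offset + _LOC.size + loc_name_len + loc_extra_len
        if data_start + csize > len(data):
            return fail(f"entry data overruns file: {name}")
        blob = data[data_start : data_start + csize]
        if method == 0:
            out = blob
        elif method == 8:
            try:
                out = zlib.decompress(blob, wbits=-15)
            except zlib.error as exc:
                return fail(f"entry {name} fails to inflate: {exc}")
        else:
            return fail(f"unsupported compression method {method} in entry {name}")
        if len(out) != usize or zlib.crc32(out) & 0xFFFFFFFF != crc:
            return fail(f"CRC32 mismatch in entry {name}")
    return CheckResult(CheckId.FORMAT_OK, True)


def run(
    path: Path,
    category: FileCategory,
    companions: CompanionSet,
    thorough: bool,
    strict: bool,
) -> list[CheckResult]:
    return [validate_zip(path, thorough=thorough)]
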