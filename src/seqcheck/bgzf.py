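"""Blocked gzip (BGZF) reading, verification and writing.

BGZF is the container underneath BAM, CSI/TBI indices and block-compressed
VCF: a concatenation of independently inflatable gzip members, each carrying a
``BC`` extra-field subfield with the total block size, terminated by a fixed
28-byte empty block that serves as an EOF marker.  Everything here works on
raw bytes so the same walker backs both the integrity checks and the fixture
generator.
"""

from __future__ import annotations

import struct
import zlib
from pathlib import Path

GZIP_MAGIC = b"\x1f\x8b"

#: The canonical 28-byte BGZF EOF block (an empty member with BSIZE=27).
BGZF_EOF = bytes.fromhex(
    "1f8b08040000000000ff0600424302001b0003000000000000000000"
)

#: Largest payload placed in one block; keeps BSIZE comfortably under 2**16.
MAX_BLOCK_PAYLOAD = 0xFF00


class BgzfError(ValueError):
    """Structural defect in a BGZF stream, with the offending byte offset."""

    def __init__(self, offset: int, message: str):
        super().__init__(f"{message} at byte offset {offset}")
        self.offset = offset


def _parse_extra_bsize(extra: bytes) -> int | None:
    """Return BSIZE from a gzip extra field's BC subfield, or None."""
    i = 0
    while i + 4 <= len(extra):
        si1, si2, slen = extra[i], extra[i + 1], struct.unpack_from("<H", extra, i + 2)[0]
        if si1 == 0x42 and si2 == 0x43 and slen == 2 and i + 6 <= len(extra):
            return struct.unpack_from("<H", extra, i + 4)[0]
        i += 4 + slen
    return None


def is_bgzf_header(head: bytes) -> bool:
    """True when the first gzip member carries a BC extra subfield."""
    if len(head) < 18 or head[:2] != GZIP_MAGIC or head[2] != 8:
        return False
    if not head[3] & 4:  # FEXTRA
        return False
    xlen = struct.unpack_from("<H", head, 10)[0]
    if len(head) < 12 + xlen:
        return False
    return _parse_extra_bsize(head[12 : 12 + xlen]) is not None


def iter_blocks(data: bytes):
    """Yield ``(offset, payload)`` per block; raise BgzfError on any defect.

    Verifies each block's CRC32 and ISIZE trailer against the inflated
    payload, i.e. a full-integrity walk.
    """
    off = 0
    n = len(data)
    while off < n:
        if n - off < 18:
            raise BgzfError(off, "truncated BGZF block header")
        if data[off : off + 2] != GZIP_MAGIC or data[off + 2] != 8:
            raise BgzfError(off, "bad BGZF block magic")
        if not data[off + 3] & 4:
            raise BgzfError(off, "gzip member without BGZF BC subfield")
        xlen = struct.unpack_from("<H", data, off + 10)[0]
        if n - off < 12 + xlen:
            raise BgzfError(off, "truncated BGZF extra field")
        bsize = _parse_extra_bsize(data[off + 12 : off + 12 + xlen])
        if bsize is None:
            raise BgzfError(off, "gzip member without BGZF BC subfield")
        total = bsize + 1
        if off + total > n:
            raise BgzfError(off, "truncated BGZF block")
        cdata = data[off + 12 + xlen : off + total - 8]
        crc_expect, isize = struct.unpack_from("<II", data, off + total - 8)
        try:
            payload = zlib.decompress(cdata, wbits=-15)
        except zlib.error as exc:
            raise BgzfError(off, f"corrupt BGZF block ({exc})") from exc
        if len(payload) != isize:
            raise BgzfError(off, "BGZF block ISIZE mismatch")
        if zlib.crc32(payload) & 0xFFFFFFFF != crc_expect:
            raise BgzfError(off, "BGZF block CRC32 mismatch")
        yield off, payload
        off += total


def decompress(data: bytes) -> bytes:
    """Inflate a whole BGZF stream (integrity-verified)."""
    return b"".join(payload for _, payload in iter_blocks(data))


def verify_stream(data: bytes) -> tuple[bool, str]:
    """Full CRC walk of every block; ``(ok, detail)``."""
    try:
        for _ in iter_blocks(data):
            pass
    except BgzfError as exc:
        return False, str(exc)
    return True, ""


def has_eof_marker(data: bytes) -> bool:
    return len(data) >= len(BGZF_EOF) and data.endswith(BGZF_EOF)


def _compress_block(chunk: bytes) -> bytes:
    comp = zlib.compressobj(6, zlib.DEFLATED, -15)
    cdata = comp.compress(chunk) + comp.flush()
    total = 18 + len(cdata) + 8
    if total - 1 > 0xFFFF:
        raise ValueError("BGZF block payload too large")
    header = (
        b"\x1f\x8b\x08\x04\x00\x00\x00\x00\x00\xff\x06\x00\x42\x43\x02\x00"
        + struct.pack("<H", total - 1)
    )
    trailer = struct.pack("<II", zlib.crc32(chunk) & 0xFFFFFFFF, len(chunk))
    return header + cdata + trailer


def compress(data: bytes, with_eof: bool = True) -> bytes:
    """Deterministically BGZF-compress ``data`` (fixed deflate level 6)."""
    out = bytearray()
    if data:
        for start in range(0, len(data), MAX_BLOCK_PAYLOAD):
            out += _compress_block(data[start : start + MAX_BLOCK_PAYLOAD])
    else:
        out += _compress_block(b"")
    if with_eof:
        out += BGZF_EOF
    return bytes(out)


def read_bytes(path: Path | str) -> bytes:
    return Path(path).read_bytes()
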