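"""The three universal checks — existence, compression, checksums — plus
checksum generation.

These run for every file regardless of format.  Checksums are computed over
the raw on-disk bytes (never the decompressed content), matching how transfer
tools such as ``md5sum`` produce sidecar files.
"""

from __future__ import annotations

import hashlib
import os
import re
import zlib
from pathlib import Path

from . import bgzf
from .detect import sniff_container
from .model import (
    DIGEST_LENGTHS,
    CheckId,
    CheckResult,
    CompanionSet,
    Compression,
    Container,
    FileCategory,
    SidecarChecksum,
)

_CHUNK = 1 << 20


class SidecarParseError(ValueError):
    """The sidecar file does not contain a recognizable digest line."""


class SidecarExistsError(FileExistsError):
    """Refusal to clobber an existing sidecar without ``overwrite``."""


def check_existence(path: Path | str) -> list[CheckResult]:
    """EXISTS → READABLE → NONEMPTY, stopping at the first failure.

    All outcomes are expressed as CheckResults; a nonexistent path yields
    exactly one failed EXISTS result.  Symlinks are followed, so a broken
    symlink counts as nonexistent.
    """
    path = Path(path)
    if not path.exists():
        return [CheckResult(CheckId.EXISTS, False, f"no such file: {path}")]
    results = [CheckResult(CheckId.EXISTS, True)]
    if not path.is_file():
        results.append(CheckResult(CheckId.READABLE, False, f"not a regular file: {path}"))
        return results
    if not os.access(path, os.R_OK):
        results.append(CheckResult(CheckId.READABLE, False, f"permission denied: {path}"))
        return results
    results.append(CheckResult(CheckId.READABLE, True))
    if path.stat().st_size == 0:
        results.append(CheckResult(CheckId.NONEMPTY, False, f"file is empty: {path}"))
    else:
        results.append(CheckResult(CheckId.NONEMPTY, True))
    return results


def _verify_gzip_members(data: bytes) -> tuple[bool, str]:
    """Walk every gzip member, inflating and letting zlib verify each
    member's CRC32/ISIZE trailer; report the offset of the bad member."""
    off = 0
    n = len(data)
    while off < n:
        if n - off < 2 or data[off : off + 2] != bgzf.GZIP_MAGIC:
            return False, f"trailing non-gzip data at byte offset {off}"
        decomp = zlib.decompressobj(31)
        try:
            decomp.decompress(data[off:])
        except zlib.error as exc:
            return False, f"corrupt gzip member at byte offset {off}: {exc}"
        if not decomp.eof:
            return False, f"truncated gzip stream in member starting at byte offset {off}"
        consumed = (n - off) - len(decomp.unused_data)
        if consumed <= 0:  # defensive; cannot regress
            return False, f"gzip walk stalled at byte offset {off}"
        off += consumed
    return True, ""


def check_compression(
    path: Path | str, category: FileCategory, thorough: bool = False
) -> CheckResult:
    """Verify that magic bytes agree with the compression the extension
    claims; in thorough mode additionally inflate every member/block and
    verify CRC32/ISIZE trailers.

    BGZF is accepted wherever plain GZIP is claimed (a BAM is a valid gzip
    stream); the BGZF-specific EOF-marker rule applies when BGZF is claimed
    by the extension or detected in the magic bytes.  Uncompressed categories
    pass with a note.
    """
    path = Path(path)
    claimed = category.compression
    if claimed is Compression.NONE:
        return CheckResult(CheckId.COMPRESSION_OK, True, "not compressed")

    try:
        sniffed = sniff_container(path)
    except OSError as exc:
        return CheckResult(CheckId.COMPRESSION_OK, False, f"cannot read file: {exc}")

    if claimed is Compression.ZIP_CONTAINER:
        if sniffed is not Container.ZIP:
            return CheckResult(
                CheckId.COMPRESSION_OK,
                False,
                f"extension claims ZIP but magic bytes look {sniffed.value}",
            )
        return CheckResult(CheckId.COMPRESSION_OK, True)

    # GZIP or BGZF claimed.
    if sniffed not in (Container.GZIP, Container.BGZF):
        return CheckResult(
            CheckId.COMPRESSION_OK,
            False,
            f"extension claims {claimed.value} but magic bytes look {sniffed.value}",
        )
    if claimed is Compression.BGZF and sniffed is not Container.BGZF:
        return CheckResult(
            CheckId.COMPRESSION_OK,
            False,
            "extension claims BGZF but the first gzip member has no BC subfield",
        )

    bgzf_mode = claimed is Compression.BGZF or sniffed is Container.BGZF
    data = path.read_bytes()
    if bgzf_mode and not bgzf.has_eof_marker(data):
        return CheckResult(CheckId.COMPRESSION_OK, False, "missing BGZF EOF marker")
    if thorough:
        ok, detail = bgzf.verify_stream(data) if bgzf_mode else _verify_gzip_members(data)
        if not ok:
            return CheckResult(CheckId.COMPRESSION_OK, False, detail)
    return CheckResult(CheckId.COMPRESSION_OK, True)


_SIDECAR_RE = re.compile(r"^([0-9A-Fa-f]+)(?: ([ *])(.*))?$")


def parse_sidecar(path: Path | str, algorithm: str) -> SidecarChecksum:
    """Parse a checksum sidecar in coreutils (``<hex>  <name>``) or
    bare-digest dialect; first non-empty line only; digest lowercased."""
    if algorithm not in DIGEST_LENGTHS:
        raise ValueError(f"unsupported digest algorithm: {algorithm}")
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    for line in text.splitlines():
        line = line.strip("\r\n")
        if not line.strip():
            continue
        match = _SIDECAR_RE.match(line)
        if match is None:
            raise SidecarParseError(f"malformed sidecar line in {path}: {line[:60]!r}")
        digest = match.group(1).lower()
        if len(digest) != DIGEST_LENGTHS[algorithm]:
            raise SidecarParseError(
                f"digest length {len(digest)} does not match {algorithm} in {path}"
            )
        return SidecarChecksum(algorithm, digest, match.group(3) or "")
    raise SidecarParseError(f"empty sidecar file: {path}")


def compute_digest(path: Path | str, algorithm: str) -> str:
    """Streaming digest of the raw on-disk bytes; constant memory."""
    if algorithm not in DIGEST_LENGTHS:
        raise ValueError(f"unsupported digest algorithm: {algorithm}")
    digest = hashlib.new(algorithm)
    with open(path, "rb") as fh:
        while chunk := fh.read(_CHUNK):
            digest.update(chunk)
    return digest.hexdigest()


def verify_checksums(
    path: Path | str, companions: CompanionSet
) -> list[CheckResult]:
    """Recompute and compare against each sidecar present.

    No sidecars is not an error: the result is a pass annotated
    "no checksum found".  Hex comparison is case-insensitive.
    """
    if not companions.checksum_sidecars:
        return [CheckResult(CheckId.CHECKSUM_OK, True, "no checksum found")]
    results = []
    for algorithm, sidecar_path in companions.checksum_sidecars:
        try:
            sidecar = parse_sidecar(sidecar_path, algorithm)
        except SidecarParseError as exc:
            results.append(
                CheckResult(CheckId.CHECKSUM_OK, False, f"malformed sidecar: {exc}")
            )
            continue
        actual = compute_digest(path, algorithm)
        if actual == sidecar.digest_hex:
            results.append(CheckResult(CheckId.CHECKSUM_OK, True))
        else:
            results.append(
                CheckResult(
                    CheckId.CHECKSUM_OK,
                    False,
                    f"{algorithm} mismatch against {sidecar_path.name}: "
                    f"file {actual}, sidecar {sidecar.digest_hex}",
                )
            )
    return results


def generate_checksum(
    path: Path | str, algorithm: str = "sha512", overwrite: bool = False
) -> Path:
    """Write ``<path>.<algorithm>`` in coreutils dialect and return it.

    Refuses to clobber an existing sidecar unless ``overwrite``.  Verifying
    immediately afterwards always passes (round-trip invariant).
    """
    path = Path(path)
    sidecar = path.with_name(path.name + f".{algorithm}")
    if sidecar.exists() and not overwrite:
        raise SidecarExistsError(f"sidecar already exists: {sidecar}")
    digest = compute_digest(path, algorithm)
    sidecar.write_text(f"{digest}  {path.name}\n", encoding="ascii")
    return sidecar
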