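"""File-type detection from extensions and magic bytes, and companion lookup.

Detection is deliberately name-based (longest registered suffix wins): the
magic-byte sniff is a separate, content-based classification, and any
disagreement between the two (say, a ``.gz`` name over plain bytes) is
surfaced later as a failed compression check rather than an exception here.
"""

from __future__ import annotations

import struct
from pathlib import Path

from . import bgzf
from .model import (
    BAM,
    CRAM,
    UNKNOWN,
    VCF,
    CompanionSet,
    Compression,
    Container,
    FileCategory,
)
from .registry import ValidatorRegistry, get_default_registry

ZIP_MAGICS = (b"PK\x03\x04", b"PK\x05\x06")


def detect_file_type(
    path: Path | str, registry: ValidatorRegistry | None = None
) -> FileCategory:
    """Classify a path by its name alone (total: never raises).

    Unmatched suffixes yield UNKNOWN with compression inferred only from a
    trailing ``.gz`` / ``.zip``.
    """
    registry = registry or get_default_registry()
    name = Path(path).name
    hit = registry.match_extension(name)
    if hit is not None:
        suffix, fmt, comp = hit
        return FileCategory(format=fmt, compression=comp, extension_matched=suffix)
    lowered = name.lower()
    if lowered.endswith(".gz"):
        comp = Compression.GZIP
    elif lowered.endswith(".zip"):
        comp = Compression.ZIP_CONTAINER
    else:
        comp = Compression.NONE
    return FileCategory(format=UNKNOWN, compression=comp, extension_matched="")


def sniff_container(path: Path | str) -> Container:
    """Classify a file's container from its magic bytes.

    GZIP members whose first member carries a BGZF ``BC`` extra subfield are
    reported as BGZF.  I/O errors propagate: an unreadable file is a different
    situation from a readable file of unknown content.
    """
    path = Path(path)
    size = path.stat().st_size
    if size == 0:
        return Container.EMPTY
    with open(path, "rb") as fh:
        head = fh.read(4096)
    if head[:2] == bgzf.GZIP_MAGIC:
        return Container.BGZF if bgzf.is_bgzf_header(head) else Container.GZIP
    if head[:4] in ZIP_MAGICS:
        return Container.ZIP
    return Container.PLAIN


def locate_companions(path: Path | str, category: FileCategory) -> CompanionSet:
    """Find existing checksum sidecars and index files next to ``path``.

    Sidecars: ``<path>.md5`` then ``<path>.sha512`` (at most one per
    algorithm by construction).  Indices: BAM → ``<path>.bai``,
    ``<stem>.bai``, ``<path>.csi``; CRAM → ``<path>.crai``; compressed VCF →
    ``<path>.tbi`` then ``<path>.csi``.  Only companions that exist are
    returned; absence is a valid empty result.
    """
    path = Path(path)
    companions = CompanionSet()
    for algorithm in ("md5", "sha512"):
        sidecar = path.with_name(path.name + f".{algorithm}")
        if sidecar.exists():
            companions.checksum_sidecars.append((algorithm, sidecar))

    candidates: list[Path] = []
    if category.format == BAM:
        candidates = [
            path.with_name(path.name + ".bai"),
            path.with_suffix(".bai"),
            path.with_name(path.name + ".csi"),
        ]
    elif category.format == CRAM:
        candidates = [path.with_name(path.name + ".crai")]
    elif category.format == VCF and category.compression in (
        Compression.GZIP,
        Compression.BGZF,
    ):
        candidates = [
            path.with_name(path.name + ".tbi"),
            path.with_name(path.name + ".csi"),
        ]
    seen = set()
    for cand in candidates:
        if cand.exists() and cand not in seen:
            companions.index_files.append(cand)
            seen.add(cand)
    return companions
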