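"""Shared line-streaming for validators over plain or gzip/BGZF files."""

from __future__ import annotations

import gzip
import zlib
from pathlib import Path

from .. import bgzf
from ..model import Compression, FileCategory

#: Exceptions signalling a decompression failure mid-stream.
STREAM_ERRORS = (OSError, EOFError, zlib.error, gzip.BadGzipFile)


def _is_gzipped(path: Path, category: FileCategory) -> bool:
    if category.compression in (Compression.GZIP, Compression.BGZF):
        return True
    with open(path, "rb") as fh:
        return fh.read(2) == bgzf.GZIP_MAGIC


def iter_lines(path: Path | str, category: FileCategory):
    """Yield decoded lines (CRLF/LF stripped) from a possibly gzipped file.

    Decoding is latin-1 so that arbitrary bytes surface as characters the
    grammar rules can reject rather than as codec errors.
    """
    path = Path(path)
    opener = gzip.open if _is_gzipped(path, category) else open
    with opener(path, "rb") as fh:
        for raw in fh:
            line = raw.decode("latin-1")
            if line.endswith("\n"):
                line = line[:-1]
            if line.endswith("\r"):
                line = line[:-1]
            yield line
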