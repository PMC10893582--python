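"""Core result and category types shared by every validator.

A validation run is a pipeline of named checks per file: the three universal
checks (existence, compression, checksum) followed by a format-specific check
and, for indexed container formats, an index-companionship check.  Each check
produces a :class:`CheckResult`; a file's :class:`FileReport` aggregates them
into a PASS/FAIL verdict.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

# Format names are open strings, not a closed enum, so that new formats can be
# registered at runtime (see seqcheck.registry).  These constants cover the
# built-in set.
FASTQ = "fastq"
SAM = "sam"
BAM = "bam"
CRAM = "cram"
VCF = "vcf"
ZIP = "zip"
UNKNOWN = "unknown"


class Compression(enum.Enum):
    """Compression state claimed by a file's extension."""

    NONE = "none"
    GZIP = "gzip"
    BGZF = "bgzf"
    ZIP_CONTAINER = "zip"


class Container(enum.Enum):
    """Container detected from a file's magic bytes."""

    PLAIN = "plain"
    GZIP = "gzip"
    BGZF = "bgzf"
    ZIP = "zip"
    EMPTY = "empty"


class CheckId(enum.Enum):
    EXISTS = "EXISTS"
    READABLE = "READABLE"
    NONEMPTY = "NONEMPTY"
    COMPRESSION_OK = "COMPRESSION_OK"
    CHECKSUM_OK = "CHECKSUM_OK"
    FORMAT_OK = "FORMAT_OK"
    INDEX_PRESENT = "INDEX_PRESENT"


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class CheckResult:
    """Outcome of one named check.

    ``detail`` is empty for a clean pass; a failed check always carries a
    human-readable reason naming the offending byte offset, line number or
    companion file where applicable.  ``severity=WARNING`` marks advisory
    checks (e.g. a missing index) that do not flip the file verdict unless
    strict mode is on.
    """

    check_id: CheckId
    passed: bool
    detail: str = ""
    severity: Severity = Severity.ERROR


@dataclass(frozen=True)
class FileCategory:
    """Detected type of a path: format, claimed compression, matched suffix."""

    format: str
    compression: Compression
    extension_matched: str


@dataclass
class CompanionSet:
    """Existing sidecar checksums and index files found next to a path."""

    checksum_sidecars: list[tuple[str, Path]] = field(default_factory=list)
    index_files: list[Path] = field(default_factory=list)


@dataclass(frozen=True)
class SidecarChecksum:
    algorithm: str  # "md5" | "sha512"
    digest_hex: str  # lowercase
    referenced_name: str = ""


@dataclass
class FastqStats:
    record_count: int = 0
    first_bad_line: int | None = None


@dataclass
class AlignmentHeaderInfo:
    has_hd: bool = False
    hd_version: str | None = None
    reference_sequences: list[tuple[str, int]] = field(default_factory=list)
    read_seen: bool = False


@dataclass
class VcfHeaderInfo:
    fileformat: str = ""
    column_count: int = 0
    sample_names: list[str] = field(default_factory=list)
    record_count: int = 0


@dataclass
class FileReport:
    """All check results for one file, in pipeline order, plus the verdict."""

    path: str
    category: FileCategory
    checks: list[CheckResult]
    verdict: str  # "PASS" | "FAIL"
    warnings: int

    @property
    def passed(self) -> bool:
        return self.verdict == "PASS"

    def first_failure(self) -> CheckResult | None:
        for c in self.checks:
            if not c.passed and c.severity is Severity.ERROR:
                return c
        for c in self.checks:
            if not c.passed:
                return c
        return None


@dataclass
class RunSummary:
    reports: list[FileReport]
    n_pass: int
    n_fail: int
    exit_code: int


DIGEST_LENGTHS = {"md5": 32, "sha512": 128}
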