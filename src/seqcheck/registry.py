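"""Validator registry: the two mappings that make the tool extensible.

Supporting a new file format requires exactly two edits — register an
extension (suffix → format name + claimed compression) and register a
validator callable (format name → function).  Nothing else in the pipeline
dispatches on format names directly.

A validator callable has the signature::

    fn(path, category, companions, thorough, strict) -> list[CheckResult]

and is invoked only after the universal checks (existence, compression,
checksum) have passed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

from .model import (
    BAM,
    CRAM,
    FASTQ,
    SAM,
    UNKNOWN,
    VCF,
    ZIP,
    CheckResult,
    Compression,
    CompanionSet,
    FileCategory,
)

ValidatorFn = Callable[
    [Path, FileCategory, CompanionSet, bool, bool], list[CheckResult]
]


class ValidatorRegistry:
    def __init__(self) -> None:
        self._extensions: dict[str, tuple[str, Compression]] = {}
        self._validators: dict[str, ValidatorFn] = {}

    def register_extension(
        self, suffix: str, fmt: str, compression: Compression
    ) -> None:
        """Map a filename suffix (e.g. ``.fastq.gz``) to a format."""
        if not suffix.startswith("."):
            raise ValueError(f"suffix must start with '.': {suffix!r}")
        self._extensions[suffix.lower()] = (fmt, compression)

    def register_validator(self, fmt: str, fn: ValidatorFn) -> None:
        self._validators[fmt] = fn

    def unregister_format(self, fmt: str) -> None:
        """Remove a format entirely; its files fall back to UNKNOWN."""
        self._validators.pop(fmt, None)
        for suffix in [s for s, (f, _) in self._extensions.items() if f == fmt]:
            del self._extensions[suffix]

    def match_extension(self, name: str) -> tuple[str, str, Compression] | None:
        """Longest-suffix, case-insensitive match; None when nothing matches."""
        lowered = name.lower()
        best: tuple[str, str, Compression] | None = None
        for suffix, (fmt, comp) in self._extensions.items():
            if lowered.endswith(suffix):
                if best is None or len(suffix) > len(best[0]):
                    best = (suffix, fmt, comp)
        return best

    def validator_for(self, fmt: str) -> ValidatorFn | None:
        return self._validators.get(fmt)

    def known_formats(self) -> set[str]:
        return set(self._validators)

    def copy(self) -> "ValidatorRegistry":
        clone = ValidatorRegistry()
        clone._extensions = dict(self._extensions)
        clone._validators = dict(self._validators)
        return clone


def default_registry() -> ValidatorRegistry:
    """Registry pre-populated with the built-in formats and validators."""
    # Imported here to keep validator modules free of registry imports.
    from .validators import alignment, archive, fastq, vcf

    reg = ValidatorRegistry()
    for suffix, fmt, comp in [
        (".fastq", FASTQ, Compression.NONE),
        (".fq", FASTQ, Compression.NONE),
        (".fastq.gz", FASTQ, Compression.GZIP),
        (".fq.gz", FASTQ, Compression.GZIP),
        (".sam", SAM, Compression.NONE),
        (".bam", BAM, Compression.BGZF),
        (".cram", CRAM, Compression.NONE),
        (".vcf", VCF, Compression.NONE),
        (".vcf.gz", VCF, Compression.GZIP),
        (".zip", ZIP, Compression.ZIP_CONTAINER),
    ]:
        reg.register_extension(suffix, fmt, comp)
    reg.register_validator(FASTQ, fastq.run)
    reg.register_validator(SAM, alignment.run)
    reg.register_validator(BAM, alignment.run)
    reg.register_validator(CRAM, alignment.run)
    reg.register_validator(VCF, vcf.run)
    reg.register_validator(ZIP, archive.run)
    return reg


_default: ValidatorRegistry | None = None


def get_default_registry() -> ValidatorRegistry:
    global _default
    if _default is None:
        _default = default_registry()
    return _default


__all__ = [
    "ValidatorRegistry",
    "ValidatorFn",
    "default_registry",
    "get_default_registry",
    "UNKNOWN",
]
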