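"""Add a new file format with exactly two registry entries.

The engine dispatches purely through the registry's two mappings
(extension → format, format → validator), so supporting a new type never
touches the pipeline.  Here a toy ``.pep`` peptide-list format gets a
validator that accepts files of alphabetic lines; the file then flows through
the full pipeline — existence, compression, checksum sidecars and all.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from seqcheck import CheckId, CheckResult, Compression, default_registry, validate_file


def validate_peptides(path, category, companions, thorough, strict):
    lines = path.read_text().split()
    ok = bool(lines) and all(line.isalpha() for line in lines)
    detail = "" if ok else "non-alphabetic peptide line"
    return [CheckResult(CheckId.FORMAT_OK, ok, detail)]


registry = default_registry()
registry.register_extension(".pep", "peptide", Compression.NONE)
registry.register_validator("peptide", validate_peptides)

with TemporaryDirectory() as tmp:
    good = Path(tmp) / "panel.pep"
    good.write_text("MKTAYIAKQR\nLVVSTQTALA\n")
    bad = Path(tmp) / "broken.pep"
    bad.write_text("MKTAYIAKQR\nLVV5TQT:LA\n")
    for path in (good, bad):
        report = validate_file(path, registry=registry)
        print(f"{report.verdict}\t{Path(report.path).name}\tformat={report.category.format}")
        for check in report.checks:
            print(f"    {check.check_id.value:15s} {'ok' if check.passed else 'FAIL'} {check.detail}")
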