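"""Validate a mixed batch of files and read the per-check report.

Builds a handful of synthetic files — a sound FASTQ and BAM, a BAM whose
BGZF EOF marker was stripped (the classic signature of an interrupted
transfer), and a VCF with a malformed variant record — then runs the full
pipeline (existence → compression → checksum → format) over all of them in
one pass.

Each output line is ``PASS/FAIL <path> <format or first failed check>``; the
summary line counts files whose every error-severity check passed.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from seqcheck import format_report, validate_paths
from seqcheck.fixtures import FixtureSpec, make_fixture

with TemporaryDirectory() as tmp:
    work = Path(tmp)
    paths = [
        make_fixture(FixtureSpec("fastq", seed=1, n_records=50), work),
        make_fixture(FixtureSpec("bam", seed=1, n_records=50), work),
        make_fixture(
            FixtureSpec("bam", seed=2, n_records=50, corruption="STRIP_EOF_BLOCK"), work
        ),
        make_fixture(FixtureSpec("vcf", seed=3, n_records=20, corruption="BAD_POS"), work),
    ]
    summary = validate_paths(paths, threads=4, thorough=True)
    print(format_report(summary, style="text"))
    print()
    print("exit code:", summary.exit_code, "(0 = all files valid, 1 = failures)")
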