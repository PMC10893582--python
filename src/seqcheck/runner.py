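"""Per-file validation pipeline and multi-file orchestration.

Every file runs the same staged pipeline — existence → compression →
checksum → format-specific dispatch — and a failure at any stage suppresses
the later stages for that file.  Multiple files are validated independently
(optionally across a thread pool); reports are always emitted in input order
and are identical to a serial run.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path

from .detect import detect_file_type, locate_companions
from .integrity import check_compression, check_existence, verify_checksums
from .model import (
    UNKNOWN,
    CheckId,
    CheckResult,
    FileReport,
    RunSummary,
    Severity,
)
from .registry import ValidatorRegistry, get_default_registry

logger = logging.getLogger(__name__)


class UsageError(ValueError):
    """Invalid invocation (e.g. empty path list)."""


def _finish(path: str, category, checks: list[CheckResult]) -> FileReport:
    failed = any(
        not c.passed and c.severity is Severity.ERROR for c in checks
    )
    warnings = sum(
        1 for c in checks if c.severity is Severity.WARNING and (not c.passed or c.detail)
    )
    report = FileReport(
        path=path,
        category=category,
        checks=checks,
        verdict="FAIL" if failed else "PASS",
        warnings=warnings,
    )
    for check in checks:
        logger.debug(
            "check path=%s id=%s passed=%s detail=%s",
            path,
            check.check_id.value,
            check.passed,
            check.detail,
        )
    return report


def validate_file(
    path: Path | str,
    thorough: bool = False,
    strict: bool = False,
    registry: ValidatorRegistry | None = None,
) -> FileReport:
    """Run the full staged pipeline on one file."""
    registry = registry or get_default_registry()
    path = Path(path)
    category = detect_file_type(path, registry)
    checks = list(check_existence(path))
    if any(not c.passed for c in checks):
        return _finish(str(path), category, checks)

    compression = check_compression(path, category, thorough=thorough)
    checks.append(compression)
    if not compression.passed:
        return _finish(str(path), category, checks)

    companions = locate_companions(path, category)
    checksum_results = verify_checksums(path, companions)
    checks.extend(checksum_results)
    if any(not c.passed for c in checksum_results):
        return _finish(str(path), category, checks)

    validator = registry.validator_for(category.format)
    if category.format == UNKNOWN or validator is None:
        checks.append(
            CheckResult(
                CheckId.FORMAT_OK,
                True,
                "no validator for type",
                Severity.WARNING,
            )
        )
        return _finish(str(path), category, checks)

    try:
        checks.extend(validator(path, category, companions, thorough, strict))
    except Exception as exc:  # a validator bug must not take down the run
        logger.exception("validator for %s raised on %s", category.format, path)
        checks.append(
            CheckResult(CheckId.FORMAT_OK, False, f"validator error: {exc}")
        )
    return _finish(str(path), category, checks)


def validate_paths(
    paths: list[Path | str],
    threads: int = 1,
    thorough: bool = False,
    strict: bool = False,
    registry: ValidatorRegistry | None = None,
) -> RunSummary:
    """Validate many files, optionally concurrently; reports in input order.

    One file's failure never aborts the others; the summary exit code is 0
    iff every file passed.
    """
    if not paths:
        raise UsageError("no paths given")
    if threads < 1:
        raise UsageError(f"threads must be >= 1, got {threads}")
    registry = registry or get_default_registry()

    def work(p):
        return validate_file(p, thorough=thorough, strict=strict, registry=registry)

    if threads == 1 or len(paths) == 1:
        reports = [work(p) for p in paths]
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            reports = list(pool.map(work, paths))

    n_pass = sum(1 for r in reports if r.passed)
    n_fail = len(reports) - n_pass
    return RunSummary(
        reports=reports,
        n_pass=n_pass,
        n_fail=n_fail,
        exit_code=0 if n_fail == 0 else 1,
    )


def format_report(summary: RunSummary, style: str = "text") -> str:
    """Render a RunSummary as a human-readable table or stable JSON."""
    if style == "text":
        lines = []
        for report in summary.reports:
            if report.passed:
                lines.append(f"PASS\t{report.path}\t{report.category.format}")
            else:
                failure = report.first_failure()
                assert failure is not None
                lines.append(
                    f"FAIL\t{report.path}\t{failure.check_id.value}: {failure.detail}"
                )
        lines.append(
            f"passed {summary.n_pass} of {summary.n_pass + summary.n_fail}"
        )
        return "\n".join(lines)
    if style == "json":
        payload = {
            "reports": [
                {
                    "path": r.path,
                    "format": r.category.format,
                    "compression": r.category.compression.value,
                    "verdict": r.verdict,
                    "warnings": r.warnings,
                    "checks": [
                        {
                            "check": c.check_id.value,
                            "passed": c.passed,
                            "severity": c.severity.value,
                            "detail": c.detail,
                        }
                        for c in r.checks
                    ],
                }
                for r in summary.reports
            ],
            "n_pass": summary.n_pass,
            "n_fail": summary.n_fail,
            "exit_code": summary.exit_code,
        }
        return json.dumps(payload, indent=2)
    raise UsageError(f"unknown report style: {style}")
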