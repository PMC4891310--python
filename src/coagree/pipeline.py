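"""End-to-end analysis: QC filtering -> agreement per variable/stratum -> trending.

:func:`run_analysis` composes the stages into an :class:`AnalysisReport`
mirroring the layout of a method-comparison report: one agreement row
per variable (ci, svi, svri, svv and the back-calculated heart rate)
and stratum (overall plus each time point), one trending block for the
primary variable, a QC accounting that reconciles exactly with the
input, and provenance (policy/options hash, seed, versions).  Strata
with too few pairs are reported as unavailable, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .agreement import HR_BACKCALC, OVERALL, MethodComparison, MethodComparisonResults
from .datasets import (MeasurementRecord, PairedSample, QcPolicy, TIMEPOINT_ORDER,
                       clean_samples, pair_and_filter, qc_summary, samples_to_frame)
from .exceptions import DegenerateTestError, EmptyAfterQcError, InsufficientDataError
from .trending import TrendAnalysis, TrendingResults

logger = logging.getLogger(__name__)

#: frozen report CSV column layout
REPORT_COLUMNS = (
    "variable", "stratum", "n", "status",
    "mean_ref", "mean_test", "bias", "sd_diff", "ci_low", "ci_high",
    "loa_low", "loa_high", "loa_low_pct", "loa_high_pct",
    "pct_error", "pct_error_acceptable", "cv_ref", "cv_test",
    "normality_p_ref", "normality_p_test", "location_test", "location_p",
    "correlation_method", "r", "correlation_p",
)

DEFAULT_VARIABLES = ("ci", "svi", "svri", "svv", HR_BACKCALC)


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable analysis settings (all seed-free; analysis is deterministic)."""

    variables: tuple[str, ...] = DEFAULT_VARIABLES
    trending_variable: str = "ci"
    orientation: str = "ref_minus_test"
    min_pairs_agreement: int = 2
    min_pairs_tests: int = 3
    exclusion_fraction: float = 0.10
    exclusion_threshold: float | None = None
    polar_limit_deg: float = 30.0
    pct_error_limit: float = 30.0


@dataclass(frozen=True)
class StratumUnavailable:
    """Placeholder row for a stratum with too few QC-clean pairs."""

    variable: str
    stratum: str
    n: int
    reason: str

    def to_row(self) -> dict:
        return {"variable": self.variable, "stratum": self.stratum,
                "n": self.n, "status": f"unavailable: {self.reason}"}


@dataclass(frozen=True)
class AnalysisReport:
    """All agreement/trending results plus QC accounting and provenance."""

    agreement: Mapping[tuple[str, str], MethodComparisonResults | StratumUnavailable]
    trending: TrendingResults | None
    samples: tuple[PairedSample, ...]
    qc: Mapping[str, int]
    provenance: Mapping[str, object]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for result in self.agreement.values():
            row = {c: None for c in REPORT_COLUMNS}
            cells = result.to_row()
            row.update(cells)
            if "status" not in cells:
                row["status"] = "ok"
            rows.append(row)
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)

    def summary(self) -> str:
        parts = [
            f"coagree analysis report (v{self.provenance.get('version')})",
            f"pairs: {self.qc['n_pairs']} total, {self.qc['n_clean']} QC-clean "
            f"(sbp_discrepancy {self.qc['sbp_discrepancy']}, "
            f"dpdt_exceeded {self.qc['dpdt_exceeded']}, "
            f"replicate_unresolved {self.qc['replicate_unresolved']})",
            "",
        ]
        for result in self.agreement.values():
            if isinstance(result, StratumUnavailable):
                parts.append(f"{result.variable} ({result.stratum}): unavailable ({result.reason})")
            else:
                parts.append(result.summary())
            parts.append("")
        if self.trending is not None:
            parts.append(self.trending.summary())
        return "\n".join(parts)


def _provenance(policy: QcPolicy, options: AnalysisOptions, seed: int | None) -> dict:
    payload = {"policy": asdict(policy), "options": asdict(options)}
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
    return {
        "version": __version__,
        "config_hash": digest[:16],
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def run_analysis(
    records: Iterable[MeasurementRecord],
    policy: QcPolicy | None = None,
    options: AnalysisOptions | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run QC, agreement and trending over a raw measurement dataset.

    Deterministic given its inputs (``seed`` is recorded in provenance
    only; the analysis itself draws no random numbers).  Raises
    :class:`EmptyAfterQcError`, listing the per-rule counts, when no
    QC-clean pair remains.
    """
    records = list(records)
    if not records:
        raise EmptyAfterQcError("dataset is empty")
    policy = policy or QcPolicy()
    options = options or AnalysisOptions()

    samples = pair_and_filter(records, policy)
    qc = qc_summary(samples)
    usable = clean_samples(samples)
    if not usable:
        raise EmptyAfterQcError(
            "no QC-clean pairs remain; removed by rule: "
            + ", ".join(f"{k}={qc[k]}" for k in ("sbp_discrepancy", "dpdt_exceeded", "replicate_unresolved"))
        )

    strata = [OVERALL] + [tp.value for tp in TIMEPOINT_ORDER]
    agreement: dict[tuple[str, str], MethodComparisonResults | StratumUnavailable] = {}
    for variable in options.variables:
        for stratum in strata:
            model = MethodComparison.from_samples(
                usable, variable, None if stratum == OVERALL else stratum,
                orientation=options.orientation,
                pct_error_limit=options.pct_error_limit,
            )
            n = model.ref.size
            if n < options.min_pairs_agreement:
                agreement[(variable, stratum)] = StratumUnavailable(
                    variable, stratum, n, f"fewer than {options.min_pairs_agreement} pairs")
                continue
            run_tests = n >= options.min_pairs_tests
            try:
                agreement[(variable, stratum)] = model.fit(run_tests=run_tests)
            except DegenerateTestError as exc:
                logger.warning("degenerate paired test for %s (%s): %s", variable, stratum, exc)
                agreement[(variable, stratum)] = model.fit(run_tests=False)

    trending: TrendingResults | None = None
    try:
        trending = TrendAnalysis(
            usable, options.trending_variable,
            exclusion_fraction=options.exclusion_fraction,
            exclusion_threshold=options.exclusion_threshold,
            limit_deg=options.polar_limit_deg,
        ).fit()
    except InsufficientDataError as exc:
        logger.warning("trending unavailable: %s", exc)

    return AnalysisReport(
        agreement=agreement, trending=trending, samples=tuple(samples),
        qc=qc, provenance=_provenance(policy, options, seed),
    )


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

_FLOAT_FORMAT = "%.10g"


def write_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report CSVs (deterministic byte-for-byte given equal inputs).

    Emits ``report.csv`` (agreement rows), ``trending.csv``,
    ``polar_points.csv``, per-variable ``bland_altman_<var>.csv``
    coordinate files, ``paired_samples.csv``, ``qc_summary.csv`` and
    ``provenance.json`` (the only file carrying a timestamp).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
        written[name] = path

    save("report.csv", report.to_frame())
    save("paired_samples.csv", samples_to_frame(report.samples, clean_only=False))
    save("qc_summary.csv", pd.DataFrame([report.qc]))
    for (variable, stratum), result in report.agreement.items():
        if stratum == OVERALL and isinstance(result, MethodComparisonResults):
            save(f"bland_altman_{variable}.csv", result.table)
    if report.trending is not None:
        save("trending.csv", pd.DataFrame([report.trending.to_row()]))
        save("polar_points.csv", report.trending.to_frame())
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(dict(report.provenance), indent=2, default=str) + "\n")
    written["provenance.json"] = prov_path
    return written
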