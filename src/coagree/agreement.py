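"""Bland-Altman agreement, percentage error and paired comparison tests.

The central object is :class:`MethodComparison`, a model built from the
paired reference/test values of one variable in one stratum, whose
:meth:`~MethodComparison.fit` returns a :class:`MethodComparisonResults`
carrying

* the Bland-Altman statistics: bias (mean of reference - test
  differences), SD of the differences (n-1 denominator), the t-based
  95 % confidence interval of the bias, and limits of agreement
  bias +/- 1.96*SD both in absolute units and as Bland-Altman applied to
  the per-pair percent differences relative to the reference reading;
* the percentage error 100 * 1.96 * SD / pooled mean, with the
  conventional 30 % clinical-acceptability verdict;
* per-method coefficients of variation and means;
* the paired location test and correlation, gated by a
  Kolmogorov-Smirnov normality check (estimated moments, alpha 0.05) on
  each method's values: paired t + Pearson when both pass, Wilcoxon
  signed-rank + Spearman otherwise.

Module-level functions (:func:`differences`, :func:`bland_altman`,
:func:`percentage_error`, :func:`paired_comparison`,
:func:`back_calculate_hr`) expose the individual operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import PairedSample, Timepoint
from .exceptions import DegenerateTestError, InsufficientDataError

OVERALL = "overall"

#: z quantile fixed by the limits-of-agreement convention
LOA_Z = 1.96

#: derived variable: reference HR vs. the heart rate the test monitor's
#: CI/SVI ratio implies (CI*1000/SVI)
HR_BACKCALC = "hr_calc"


def back_calculate_hr(ci, svi):
    """Heart rate implied by a CI (L/min/m^2) and SVI (mL/m^2): CI*1000/SVI."""
    ci = np.asarray(ci, dtype=float)
    svi = np.asarray(svi, dtype=float)
    if np.any(svi <= 0):
        raise ValueError("svi must be strictly positive to back-calculate heart rate")
    out = ci * 1000.0 / svi
    return float(out) if out.ndim == 0 else out


def _extract(samples: Iterable[PairedSample], variable: str,
             stratum: str | Timepoint | None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(stratum, Timepoint):
        stratum = stratum.value
    ref_values, test_values, subjects = [], [], []
    for sample in samples:
        if not sample.is_clean:
            continue
        if stratum not in (None, OVERALL) and sample.timepoint.value != stratum:
            continue
        if variable == HR_BACKCALC:
            r = sample.ref.get("hr")
            ci, svi = sample.test.get("ci"), sample.test.get("svi")
            t = ci * 1000.0 / svi if (ci is not None and svi is not None and svi > 0) else None
        else:
            r, t = sample.ref.get(variable), sample.test.get(variable)
        if r is None or t is None:
            continue
        ref_values.append(r)
        test_values.append(t)
        subjects.append(sample.subject_id)
    return np.asarray(ref_values, float), np.asarray(test_values, float), subjects


class PercentageError(NamedTuple):
    value: float
    acceptable: bool


def percentage_error(sd_diff: float, mean_ref: float, mean_test: float,
                     limit: float = 30.0) -> PercentageError:
    """Percentage error 100*1.96*SD(differences)/pooled mean, with verdict.

    Values above ``limit`` (30 % by convention) are clinically not
    acceptable.  Raises ``ValueError`` on a non-positive pooled mean.
    """
    pooled = (mean_ref + mean_test) / 2.0
    if pooled <= 0:
        raise ValueError(f"percentage error undefined: non-positive pooled mean {pooled}")
    value = 100.0 * LOA_Z * sd_diff / pooled
    return PercentageError(value, value <= limit)


def percentage_error_from_loa(loa_low: float, loa_high: float,
                              mean_ref: float, mean_test: float,
                              limit: float = 30.0) -> PercentageError:
    """Percentage error reconstructed from published limits of agreement.

    Uses the LoA half-width (high - low)/2 as 1.96*SD; lets the headline
    verdict be recomputed from a report's printed bias, LoA and means.
    """
    half_width = (loa_high - loa_low) / 2.0
    return percentage_error(half_width / LOA_Z, mean_ref, mean_test, limit=limit)


@dataclass(frozen=True)
class MethodComparisonResults:
    """Agreement and comparison statistics for one variable in one stratum."""

    variable: str
    stratum: str
    n: int
    mean_ref: float
    mean_test: float
    bias: float
    sd_diff: float
    ci_bias: tuple[float, float]
    loa: tuple[float, float]
    bias_pct: float          # mean of per-pair percent differences (ref basis)
    sd_diff_pct: float
    loa_pct: tuple[float, float]
    pct_error: float
    pct_error_acceptable: bool
    cv_ref: float
    cv_test: float
    table: pd.DataFrame      # per-pair ref, test, pair_mean, diff, pct_diff
    normality_p_ref: float | None = None
    normality_p_test: float | None = None
    normal: bool | None = None
    location_test_used: str | None = None
    location_p: float | None = None
    correlation_method: str | None = None
    r: float | None = None
    correlation_p: float | None = None

    @property
    def mean_difference(self) -> float:
        return self.bias

    @property
    def ci_difference(self) -> tuple[float, float]:
        return self.ci_bias

    def to_row(self) -> dict:
        """Flat dict matching the frozen report CSV layout."""
        return {
            "variable": self.variable, "stratum": self.stratum, "n": self.n,
            "mean_ref": self.mean_ref, "mean_test": self.mean_test,
            "bias": self.bias, "sd_diff": self.sd_diff,
            "ci_low": self.ci_bias[0], "ci_high": self.ci_bias[1],
            "loa_low": self.loa[0], "loa_high": self.loa[1],
            "loa_low_pct": self.loa_pct[0], "loa_high_pct": self.loa_pct[1],
            "pct_error": self.pct_error,
            "pct_error_acceptable": int(self.pct_error_acceptable),
            "cv_ref": self.cv_ref, "cv_test": self.cv_test,
            "normality_p_ref": self.normality_p_ref,
            "normality_p_test": self.normality_p_test,
            "location_test": self.location_test_used,
            "location_p": self.location_p,
            "correlation_method": self.correlation_method,
            "r": self.r, "correlation_p": self.correlation_p,
        }

    def summary(self) -> str:
        lines = [
            f"Method comparison: {self.variable} ({self.stratum}), n = {self.n}",
            "-" * 58,
            f"mean reference        {self.mean_ref:12.4g}   CV {self.cv_ref:6.1f} %",
            f"mean test             {self.mean_test:12.4g}   CV {self.cv_test:6.1f} %",
            f"bias (ref - test)     {self.bias:12.4g}   95% CI [{self.ci_bias[0]:.4g}, {self.ci_bias[1]:.4g}]",
            f"SD of differences     {self.sd_diff:12.4g}",
            f"limits of agreement   [{self.loa[0]:.4g}, {self.loa[1]:.4g}]"
            f"   ([{self.loa_pct[0]:.1f}, {self.loa_pct[1]:.1f}] %)",
            f"percentage error      {self.pct_error:10.1f} %   "
            + ("acceptable (<= 30 %)" if self.pct_error_acceptable else "NOT acceptable (> 30 %)"),
        ]
        if self.location_test_used is not None:
            lines.append(
                f"{self.location_test_used:<14}        p = {self.location_p:.4g}"
                f"   (KS normality p: ref {self.normality_p_ref:.3g}, test {self.normality_p_test:.3g})"
            )
            lines.append(f"{self.correlation_method:<14}        r = {self.r:.3f}, p = {self.correlation_p:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bland-Altman scatter with bias and limit-of-agreement lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.table["pair_mean"], self.table["diff"], s=18, alpha=0.8)
        ax.axhline(self.bias, color="k", lw=1.2)
        for y in self.loa:
            ax.axhline(y, color="k", lw=1.0, ls="--")
        ax.set_xlabel(f"pair mean {self.variable}")
        ax.set_ylabel("reference - test")
        ax.set_title(f"Bland-Altman: {self.variable} ({self.stratum})")
        return ax


class MethodComparison:
    """Paired-measurement agreement model for one variable and stratum.

    Parameters
    ----------
    ref, test : array-like
        Paired readings of the two monitors, in matching order.
    variable, stratum : str
        Labels carried through to the results and report rows.
    orientation : {"ref_minus_test", "test_minus_ref"}
        Sign convention of the differences; the default matches the
        reference-minus-test presentation of method-comparison tables.
    """

    def __init__(self, ref, test, variable: str = "ci", stratum: str = OVERALL,
                 orientation: str = "ref_minus_test",
                 normality_alpha: float = 0.05, pct_error_limit: float = 30.0):
        self.ref = np.asarray(ref, dtype=float)
        self.test = np.asarray(test, dtype=float)
        if self.ref.shape != self.test.shape or self.ref.ndim != 1:
            raise ValueError("ref and test must be 1-d arrays of equal length")
        if orientation not in ("ref_minus_test", "test_minus_ref"):
            raise ValueError(f"unknown orientation {orientation!r}")
        self.variable = variable
        self.stratum = stratum if isinstance(stratum, str) else stratum.value
        self.orientation = orientation
        self.normality_alpha = normality_alpha
        self.pct_error_limit = pct_error_limit

    @classmethod
    def from_samples(cls, samples: Iterable[PairedSample], variable: str = "ci",
                     stratum: str | Timepoint | None = None, **kwargs) -> "MethodComparison":
        ref, test, _ = _extract(samples, variable, stratum)
        label = OVERALL if stratum in (None, OVERALL) else (
            stratum.value if isinstance(stratum, Timepoint) else stratum
        )
        return cls(ref, test, variable=variable, stratum=label, **kwargs)

    # -- pieces -----------------------------------------------------------

    def differences(self) -> pd.DataFrame:
        """Per-pair table: ref, test, pair mean, difference, percent difference.

        The percent difference is taken relative to the reference
        reading, the convention for expressing agreement as a
        percentage of the reference method.
        """
        if self.ref.size < 2:
            raise InsufficientDataError(
                f"{self.variable} ({self.stratum}): need >= 2 pairs, have {self.ref.size}"
            )
        sign = 1.0 if self.orientation == "ref_minus_test" else -1.0
        diff = sign * (self.ref - self.test)
        return pd.DataFrame({
            "ref": self.ref, "test": self.test,
            "pair_mean": (self.ref + self.test) / 2.0,
            "diff": diff,
            "pct_diff": 100.0 * diff / self.ref,
        })

    def _normality_gate(self) -> tuple[float, float, bool]:
        def ks_p(x: np.ndarray) -> float:
            sd = x.std(ddof=1)
            if sd == 0:  # degenerate sample: no evidence against normality
                return 1.0
            return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)

        p_ref, p_test = ks_p(self.ref), ks_p(self.test)
        return p_ref, p_test, (p_ref >= self.normality_alpha and p_test >= self.normality_alpha)

    # -- fitting ----------------------------------------------------------

    def fit(self, run_tests: bool = True) -> MethodComparisonResults:
        table = self.differences()
        n = len(table)
        diff = table["diff"].to_numpy()
        pct = table["pct_diff"].to_numpy()

        bias = float(diff.mean())
        sd = float(diff.std(ddof=1))
        t_crit = float(stats.t.ppf(0.975, n - 1))
        half = t_crit * sd / math.sqrt(n)
        loa = (bias - LOA_Z * sd, bias + LOA_Z * sd)
        bias_pct = float(pct.mean())
        sd_pct = float(pct.std(ddof=1))
        loa_pct = (bias_pct - LOA_Z * sd_pct, bias_pct + LOA_Z * sd_pct)

        mean_ref, mean_test = float(self.ref.mean()), float(self.test.mean())
        pe = percentage_error(sd, mean_ref, mean_test, limit=self.pct_error_limit)
        cv_ref = 100.0 * float(self.ref.std(ddof=1)) / mean_ref
        cv_test = 100.0 * float(self.test.std(ddof=1)) / mean_test

        extra: dict = {}
        if run_tests:
            if n < 3:
                raise InsufficientDataError(
                    f"{self.variable} ({self.stratum}): need >= 3 pairs for paired tests, have {n}"
                )
            p_ref, p_test, normal = self._normality_gate()
            if normal:
                if np.allclose(diff, 0.0):
                    location_p = 1.0  # identical methods: no evidence of a location shift
                else:
                    location_p = float(stats.ttest_rel(self.ref, self.test).pvalue)
                location_used = "paired_t"
                if np.allclose(self.ref, self.ref[0]) or np.allclose(self.test, self.test[0]):
                    r, corr_p = 0.0, 1.0
                else:
                    r_res = stats.pearsonr(self.ref, self.test)
                    r, corr_p = float(r_res.statistic), float(r_res.pvalue)
                corr_method = "pearson"
            else:
                nz = diff[diff != 0.0]
                if nz.size == 0:
                    raise DegenerateTestError(
                        f"{self.variable} ({self.stratum}): Wilcoxon undefined, all differences are zero"
                    )
                location_p = float(stats.wilcoxon(self.ref, self.test).pvalue)
                location_used = "wilcoxon"
                r_res = stats.spearmanr(self.ref, self.test)
                r, corr_p = float(r_res.statistic), float(r_res.pvalue)
                corr_method = "spearman"
            extra = dict(
                normality_p_ref=p_ref, normality_p_test=p_test, normal=normal,
                location_test_used=location_used, location_p=location_p,
                correlation_method=corr_method, r=r, correlation_p=corr_p,
            )

        return MethodComparisonResults(
            variable=self.variable, stratum=self.stratum, n=n,
            mean_ref=mean_ref, mean_test=mean_test,
            bias=bias, sd_diff=sd, ci_bias=(bias - half, bias + half), loa=loa,
            bias_pct=bias_pct, sd_diff_pct=sd_pct, loa_pct=loa_pct,
            pct_error=pe.value, pct_error_acceptable=pe.acceptable,
            cv_ref=cv_ref, cv_test=cv_test, table=table, **extra,
        )


# ---------------------------------------------------------------------------
# Operation-style wrappers
# ---------------------------------------------------------------------------

def differences(samples: Iterable[PairedSample], variable: str = "ci",
                stratum: str | Timepoint | None = None,
                orientation: str = "ref_minus_test") -> pd.DataFrame:
    """Per-pair difference/mean table for QC-clean samples of one variable."""
    return MethodComparison.from_samples(
        samples, variable, stratum, orientation=orientation
    ).differences()


def bland_altman(samples: Iterable[PairedSample], variable: str = "ci",
                 stratum: str | Timepoint | None = None,
                 **kwargs) -> MethodComparisonResults:
    """Bland-Altman agreement statistics (no paired tests; needs >= 2 pairs)."""
    return MethodComparison.from_samples(samples, variable, stratum, **kwargs).fit(run_tests=False)


def paired_comparison(samples: Iterable[PairedSample], variable: str = "ci",
                      stratum: str | Timepoint | None = None,
                      **kwargs) -> MethodComparisonResults:
    """Full fit including the normality-gated location test and correlation."""
    return MethodComparison.from_samples(samples, variable, stratum, **kwargs).fit(run_tests=True)
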