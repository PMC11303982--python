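"""Additive-genetic null expectations and deviation tests for F2 hybrids.

Under a simple additive model — two alleles per locus, Mendelian
segregation, linkage equilibrium, no dominance or epistasis — an F2
intercross of two divergent parental lines is expected to center on the
mid-parent value MP = (P1 + P2) / 2, and each locus segregates 1:2:1.
Collapsing a trait's genetic basis to one effective locus, the F2 phenotype
takes values {P1, MP, P2} with weights {1/4, 1/2, 1/4}, whose variance is
(P1 - P2)^2 / 8; with L equal-effect loci the expectation is
(P1 - P2)^2 / (8 L). Observed F2 trait means and variances are tested
against these expectations: a trait whose mean interval excludes MP, or
whose variance is inconsistent with the segregation expectation, points to
non-additive mechanisms (dominance, epistasis, transgressive segregation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .trait_io import trait_columns

__all__ = [
    "AdditiveNull",
    "build_additive_null",
    "test_mean_deviation",
    "test_variance_deviation",
    "VarianceDeviation",
]


@dataclass
class AdditiveNull:
    """Per-trait additive expectations for one F2 cross.

    All values are in the same (size-standardized residual) units as the
    trait table they were built from.
    """

    traits: list[str]
    parent1: np.ndarray
    parent2: np.ndarray
    midparent: np.ndarray
    expected_variance: np.ndarray
    n_f2: int
    n_loci: int = 1
    cross_label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.traits,
                "parent1": self.parent1,
                "parent2": self.parent2,
                "midparent": self.midparent,
                "expected_variance": self.expected_variance,
            }
        )


def build_additive_null(
    parent_values: pd.DataFrame | dict,
    n_f2: int,
    n_loci: int = 1,
    cross_label: str = "",
) -> AdditiveNull:
    """Build the additive null from the two F0 parental trait vectors.

    Parameters
    ----------
    parent_values
        Either a 2-row DataFrame (one row per parent; metadata columns
        ignored) or a mapping ``trait -> (P1, P2)``.
    n_f2
        F2 sample size the null will be tested against (must be >= 2).
    n_loci
        Effective loci per trait for the segregation-variance expectation
        ``(P1 - P2)^2 / (8 * n_loci)``; 1 is the maximal (single-locus)
        expectation.
    """
    if n_f2 < 2:
        raise ValueError(f"n_f2 must be >= 2, got {n_f2}")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if isinstance(parent_values, dict):
        traits = list(parent_values)
        p1 = np.array([parent_values[t][0] for t in traits], dtype=float)
        p2 = np.array([parent_values[t][1] for t in traits], dtype=float)
    else:
        if len(parent_values) != 2:
            raise ValueError(f"expected exactly 2 parental rows, got {len(parent_values)}")
        traits = trait_columns(parent_values)
        traits = [t for t in traits if t != "generation"]
        vals = parent_values[traits].to_numpy(dtype=float)
        p1, p2 = vals[0], vals[1]
    if not (np.isfinite(p1).all() and np.isfinite(p2).all()):
        raise ValueError("parental trait values must be finite")
    midparent = (p1 + p2) / 2.0
    expected_variance = (p1 - p2) ** 2 / (8.0 * n_loci)
    return AdditiveNull(
        traits=traits,
        parent1=p1,
        parent2=p2,
        midparent=midparent,
        expected_variance=expected_variance,
        n_f2=int(n_f2),
        n_loci=int(n_loci),
        cross_label=cross_label,
    )


def _f2_matrix(f2: pd.DataFrame, null: AdditiveNull) -> np.ndarray:
    missing = [t for t in null.traits if t not in f2.columns]
    if missing:
        raise ValueError(f"F2 table is missing trait column(s) {missing}")
    return f2[null.traits].to_numpy(dtype=float)


def test_mean_deviation(
    f2: pd.DataFrame,
    null: AdditiveNull,
    iterations: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
    method: str = "bootstrap",
) -> pd.DataFrame:
    """Test each trait's F2 mean against its mid-parent expectation.

    A percentile-bootstrap interval (or a Student-t interval with
    ``method="t"``) is placed on each trait mean; the trait deviates from
    additivity iff the interval excludes MP, with the direction (above /
    below) recorded.

    Returns a per-trait DataFrame: midparent, mean, ci_low, ci_high,
    deviation in {"above", "below", "none"}.
    """
    x = _f2_matrix(f2, null)
    n = x.shape[0]
    if n < 10:
        raise ValueError(f"need >= 10 F2 individuals, got {n}")
    alpha = (1.0 - ci) / 2.0
    means = x.mean(axis=0)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(iterations, n))
        boot_means = x[idx].mean(axis=1)  # (iterations, d)
        lo, hi = np.percentile(boot_means, [100 * alpha, 100 * (1 - alpha)], axis=0)
    elif method == "t":
        sem = x.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = _stats.t.ppf(1 - alpha, df=n - 1)
        lo, hi = means - tcrit * sem, means + tcrit * sem
    else:
        raise ValueError(f"unknown method {method!r}")
    deviation = np.where(
        null.midparent < lo, "above", np.where(null.midparent > hi, "below", "none")
    )
    return pd.DataFrame(
        {
            "trait": null.traits,
            "midparent": null.midparent,
            "mean": means,
            "ci_low": lo,
            "ci_high": hi,
            "deviation": deviation,
        }
    )


@dataclass
class VarianceDeviation:
    """Cross-level and per-trait comparison of observed vs expected F2 variance."""

    t: float
    df: float
    p_value: float
    table: pd.DataFrame
    cross_label: str = ""


def test_variance_deviation(
    f2: pd.DataFrame,
    null: AdditiveNull,
    alpha: float = 0.05,
) -> VarianceDeviation:
    """Compare observed F2 trait variances against segregation expectations.

    Cross-level: Welch's two-sample t-test of the set of observed per-trait
    variances against the set of expected variances (non-integer df). A
    positive t means observed variation exceeds the additive expectation.

    Per-trait: a two-sided chi-square variance test,
    (n - 1) s^2 / sigma0^2 ~ chi2(n - 1), flags individual traits whose
    variance is in excess (transgressive) or deficit relative to expectation.
    """
    x = _f2_matrix(f2, null)
    n = x.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 F2 individuals, got {n}")
    obs = x.var(axis=0, ddof=1)
    exp = null.expected_variance
    res = _stats.ttest_ind(obs, exp, equal_var=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp > 0, obs / exp, np.inf)
        chi2_stat = (n - 1) * np.where(exp > 0, obs / exp, np.nan)
    cdf = _stats.chi2.cdf(chi2_stat, df=n - 1)
    p_per_trait = np.where(np.isnan(chi2_stat), np.nan, 2.0 * np.minimum(cdf, 1 - cdf))
    flag = np.where(
        np.isnan(p_per_trait) | (p_per_trait >= alpha),
        "none",
        np.where(obs > exp, "excess", "deficit"),
    )
    table = pd.DataFrame(
        {
            "trait": null.traits,
            "observed_variance": obs,
            "expected_variance": exp,
            "ratio": ratio,
            "chi2_p": p_per_trait,
            "variance_flag": flag,
        }
    )
    return VarianceDeviation(
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        table=table,
        cross_label=null.cross_label,
    )
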