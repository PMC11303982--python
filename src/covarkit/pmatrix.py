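"""P-matrix estimation and the bootstrap engine for matrix statistics.

A P matrix is the phenotypic variance-covariance matrix of a set of traits
within a group of individuals — the empirical stand-in for the additive
genetic (G) matrix. This module estimates P matrices from size-standardized
residual trait tables and provides nonparametric bootstrap (resampling
individuals with replacement) point-estimate confidence intervals and
between-group difference tests for any scalar matrix statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .trait_io import trait_columns

__all__ = [
    "PMatrix",
    "BootstrapResult",
    "GroupComparison",
    "estimate_pmatrix",
    "bootstrap_statistic",
    "compare_groups",
]


@dataclass
class PMatrix:
    """Symmetric trait covariance matrix with its provenance.

    Attributes
    ----------
    matrix : (d, d) ndarray
        Covariance estimate in squared trait-residual units.
    trait_names : list of str
        Ordered trait labels for rows/columns.
    n : int
        Number of complete individual trait vectors used.
    df : int
        Denominator degrees of freedom (default n - 1).
    group_label : str
        Which group of individuals the matrix describes.
    """

    matrix: np.ndarray
    trait_names: list[str]
    n: int
    df: int
    group_label: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        d = len(self.trait_names)
        if self.matrix.shape != (d, d):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {d} trait names"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("P matrix must be symmetric (tolerance 1e-12)")
        if (np.diag(self.matrix) < -1e-12).any():
            raise ValueError("P matrix has negative diagonal entries")

    @property
    def d(self) -> int:
        return len(self.trait_names)

    def correlation(self) -> np.ndarray:
        """Correlation matrix derived from the covariances.

        Raises if any trait has zero variance (correlation undefined).
        """
        v = np.diag(self.matrix)
        zero = np.flatnonzero(v <= 0)
        if zero.size:
            names = [self.trait_names[i] for i in zero]
            raise ValueError(f"zero-variance trait(s), correlation undefined: {names}")
        s = 1.0 / np.sqrt(v)
        corr = self.matrix * np.outer(s, s)
        np.fill_diagonal(corr, 1.0)
        return corr

    def eigenvalues(self) -> np.ndarray:
        """Covariance eigenvalues, descending."""
        return np.linalg.eigvalsh(self.matrix)[::-1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.trait_names, columns=self.trait_names).to_csv(path)

    @classmethod
    def from_csv(cls, path, n: int, df: int | None = None, group_label: str = "") -> "PMatrix":
        m = pd.read_csv(path, index_col=0)
        return cls(
            matrix=m.to_numpy(dtype=float),
            trait_names=list(m.columns),
            n=n,
            df=n - 1 if df is None else df,
            group_label=group_label,
        )


def _group_matrix(
    residuals: pd.DataFrame, group, group_col: str, traits: list[str]
) -> np.ndarray:
    if group is not None:
        sub = residuals.loc[residuals[group_col] == group, traits]
        if sub.empty:
            raise ValueError(f"no rows with {group_col} == {group!r}")
    else:
        sub = residuals[traits]
    fully_missing = [t for t in traits if sub[t].isna().all()]
    if fully_missing:
        raise ValueError(f"trait(s) fully missing in group {group!r}: {fully_missing}")
    # complete-case: covariance needs complete trait vectors
    x = sub.dropna().to_numpy(dtype=float)
    return x


def estimate_pmatrix(
    residuals: pd.DataFrame,
    group=None,
    group_col: str = "group",
    traits: list[str] | None = None,
    ddof: int = 1,
) -> PMatrix:
    """Estimate the P matrix for one group of a residual trait table.

    Entry (i, j) is the sample covariance of traits i and j over the group's
    complete-case individuals, with denominator ``n - ddof``. ``ddof=1`` is
    the default; ``ddof=2`` additionally discounts the slope removed by the
    allometric standardization (a scalar factor that cancels in all
    correlation-based statistics).
    """
    traits = traits or trait_columns(residuals)
    x = _group_matrix(residuals, group, group_col, traits)
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 complete individuals, got {n} in group {group!r}")
    if ddof >= n:
        raise ValueError(f"ddof={ddof} leaves no degrees of freedom at n={n}")
    xc = x - x.mean(axis=0)
    m = (xc.T @ xc) / (n - ddof)
    m = (m + m.T) / 2.0  # exact symmetry against accumulation noise
    return PMatrix(
        matrix=m,
        trait_names=list(traits),
        n=n,
        df=n - ddof,
        group_label="(all)" if group is None else str(group),
    )


@dataclass
class BootstrapResult:
    """Percentile-bootstrap summary for one scalar matrix statistic."""

    statistic: str
    point: float
    replicates: np.ndarray
    ci_level: float
    ci_low: float
    ci_high: float
    seed: int | None
    n_failed: int = 0
    group_label: str = ""

    @property
    def iterations(self) -> int:
        return len(self.replicates) + self.n_failed


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _resolve_statistic(statistic, skewers, skewer_seed):
    """Return (name, callable PMatrix -> float)."""
    if callable(statistic):
        return getattr(statistic, "__name__", "statistic"), statistic
    from . import matrix_stats

    return statistic, matrix_stats.statistic_function(
        statistic, skewers=skewers, seed=skewer_seed
    )


def _bootstrap_replicates(
    x: np.ndarray,
    traits: list[str],
    func: Callable[[PMatrix], float],
    iterations: int,
    rng: np.random.Generator,
    ddof: int,
    group_label: str,
) -> tuple[np.ndarray, int]:
    n = x.shape[0]
    values = np.empty(iterations)
    failed = 0
    for i in range(iterations):
        idx = rng.integers(0, n, n)
        xb = x[idx]
        xc = xb - xb.mean(axis=0)
        m = (xc.T @ xc) / (n - ddof)
        m = (m + m.T) / 2.0
        try:
            values[i] = func(
                PMatrix(m, traits, n=n, df=n - ddof, group_label=group_label)
            )
        except (np.linalg.LinAlgError, ValueError):
            values[i] = np.nan
            failed += 1
    if failed > 0.2 * iterations:
        raise RuntimeError(
            f"{failed}/{iterations} bootstrap replicates failed for group "
            f"{group_label!r}; matrix likely near-singular at this sample size"
        )
    return values[np.isfinite(values)], failed


def bootstrap_statistic(
    residuals: pd.DataFrame,
    statistic,
    group=None,
    group_col: str = "group",
    iterations: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
    traits: list[str] | None = None,
    ddof: int = 1,
    skewers=None,
) -> BootstrapResult:
    """Bootstrap a matrix statistic by resampling individuals within a group.

    Individuals are resampled with replacement, the P matrix re-estimated and
    the statistic recomputed on each replicate; the CI is the percentile
    interval at level ``ci``. Skewer-based statistics reuse one fixed skewer
    ensemble across replicates so replicate-to-replicate variation reflects
    sampling, not Monte Carlo, noise. Fully reproducible under ``seed``.
    """
    if iterations < 2:
        raise ValueError("iterations must be >= 2")
    traits = traits or trait_columns(residuals)
    boot_child, skewer_child = _as_seed_sequence(seed).spawn(2)
    rng = np.random.default_rng(boot_child)
    name, func = _resolve_statistic(statistic, skewers, skewer_seed=skewer_child)
    x = _group_matrix(residuals, group, group_col, traits)
    point = func(estimate_pmatrix(residuals, group, group_col, traits, ddof))
    label = "(all)" if group is None else str(group)
    values, failed = _bootstrap_replicates(x, traits, func, iterations, rng, ddof, label)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapResult(
        statistic=name,
        point=float(point),
        replicates=values,
        ci_level=ci,
        ci_low=float(lo),
        ci_high=float(hi),
        seed=seed,
        n_failed=failed,
        group_label=label,
    )


@dataclass
class GroupComparison:
    """Bootstrap difference (A - B) of one statistic between two groups."""

    statistic: str
    group_a: str
    group_b: str
    point_a: float
    point_b: float
    difference: float
    ci_level: float
    ci_low: float
    ci_high: float
    significant: bool
    replicates: np.ndarray
    seed: int | None


def compare_groups(
    residuals: pd.DataFrame,
    group_a,
    group_b,
    statistic,
    group_col: str = "group",
    iterations: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
    traits: list[str] | None = None,
    ddof: int = 1,
    skewers=None,
) -> GroupComparison:
    """Test whether a matrix statistic differs between two groups.

    Each group is resampled independently; the replicate-paired differences
    form the bootstrap distribution of (statistic_A - statistic_B). The
    difference is flagged significant iff the percentile CI excludes 0.
    """
    traits = traits or trait_columns(residuals)
    ss = _as_seed_sequence(seed)
    child_a, child_b, skewer_child = ss.spawn(3)
    if group_a == group_b:
        # self-comparison: share the resampling stream so the difference is
        # identically zero rather than pure resampling noise
        child_b = child_a
    name, func = _resolve_statistic(statistic, skewers, skewer_seed=skewer_child)

    points, reps = [], []
    for group, child in ((group_a, child_a), (group_b, child_b)):
        x = _group_matrix(residuals, group, group_col, traits)
        if x.shape[0] < 3:
            raise ValueError(f"group {group!r} has fewer than 3 complete rows")
        points.append(func(estimate_pmatrix(residuals, group, group_col, traits, ddof)))
        values, _ = _bootstrap_replicates(
            x, traits, func, iterations, np.random.default_rng(child), ddof, str(group)
        )
        reps.append(values)
    k = min(len(reps[0]), len(reps[1]))
    diff = reps[0][:k] - reps[1][:k]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(diff, [100 * alpha, 100 * (1 - alpha)])
    point_diff = points[0] - points[1]
    return GroupComparison(
        statistic=name,
        group_a=str(group_a),
        group_b=str(group_b),
        point_a=float(points[0]),
        point_b=float(points[1]),
        difference=float(point_diff),
        ci_level=ci,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        replicates=diff,
        seed=seed,
    )
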