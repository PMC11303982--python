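"""Sample-size adequacy diagnostics: ANOVA power curves and variance stabilization.

Two questions recur before trusting group comparisons at modest sample
sizes: (1) how many individuals are needed to detect a group-mean difference
of a given effect size (eta^2) with the desired power, and (2) at what
sample size does the sample-variance estimator itself settle down enough for
covariance work. The first is answered analytically with the noncentral-F
power function of one-way fixed-effects ANOVA (noncentrality
lambda = n * eta^2 / (1 - eta^2)); the second by Monte Carlo over normal
samples, where the spread of the variance estimator has the closed form
sd^2 * sqrt(2 / (n - 1)) to check against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.power import FTestAnovaPower

__all__ = [
    "anova_power",
    "min_sample_size",
    "power_grid",
    "variance_stabilization",
    "StabilizationCurve",
]


def anova_power(eta2: float, n_total: int, k_groups: int, alpha: float = 0.05) -> float:
    """Power of the one-way fixed-effects F test at total sample size ``n_total``.

    Uses noncentrality lambda = n * eta^2 / (1 - eta^2) with dfn = k - 1 and
    dfd = n - k.
    """
    if not 0 < eta2 < 1:
        raise ValueError(f"eta2 must be in (0, 1), got {eta2}")
    if k_groups < 2:
        raise ValueError("need at least 2 groups")
    if n_total <= k_groups:
        return 0.0
    lam = n_total * eta2 / (1.0 - eta2)
    dfn, dfd = k_groups - 1, n_total - k_groups
    crit = _stats.f.isf(alpha, dfn, dfd)
    return float(_stats.ncf.sf(crit, dfn, dfd, lam))


def min_sample_size(
    eta2: float,
    k_groups: int,
    alpha: float = 0.05,
    power: float = 0.8,
    cap: int = 1_000_000,
) -> tuple[int, bool]:
    """Smallest total n at which the one-way ANOVA attains the target power.

    A continuous solution from the noncentral-F power solver seeds an exact
    integer search, so the returned n satisfies power(n) >= target and
    power(n - 1) < target. Returns ``(n, capped)``; if no n <= cap reaches
    the target, ``(cap, True)`` is returned.
    """
    if not 0 < eta2 < 1:
        raise ValueError(f"eta2 must be in (0, 1), got {eta2}")
    if k_groups < 2:
        raise ValueError("need at least 2 groups")
    f_effect = np.sqrt(eta2 / (1.0 - eta2))  # Cohen's f
    try:
        guess = FTestAnovaPower().solve_power(
            effect_size=f_effect, k_groups=k_groups, alpha=alpha, power=power
        )
        n = max(int(np.floor(guess)) - 2, k_groups + 1)
    except Exception:
        n = k_groups + 1
    # walk down to the exact boundary, then up
    while n > k_groups + 1 and anova_power(eta2, n - 1, k_groups, alpha) >= power:
        n -= 1
    while anova_power(eta2, n, k_groups, alpha) < power:
        n += 1
        if n >= cap:
            return cap, True
    return n, False


def power_grid(
    eta2_values,
    k_groups: int,
    alpha: float = 0.05,
    power: float = 0.8,
    cap: int = 1_000_000,
) -> pd.DataFrame:
    """Minimum total n across a grid of eta^2 effect sizes."""
    rows = []
    for e in eta2_values:
        n, capped = min_sample_size(e, k_groups, alpha, power, cap)
        rows.append(
            {
                "eta2": e,
                "k_groups": k_groups,
                "alpha": alpha,
                "target_power": power,
                "min_n": n,
                "capped": capped,
                "power_at_min_n": anova_power(e, n, k_groups, alpha),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StabilizationCurve:
    """Monte Carlo spread of the sample-variance estimator across sample sizes.

    ``table`` holds per-n: the SD of the variance estimator across
    replicates, its closed-form value sd^2 sqrt(2/(n-1)), and the relative
    spread (SD / true variance). ``stabilization_n`` is the smallest grid n
    whose relative spread falls below ``tolerance`` (None if never).
    """

    table: pd.DataFrame
    stabilization_n: int | None
    tolerance: float
    replicates: int
    seed: int | None


def variance_stabilization(
    mean: float,
    sd: float,
    n_grid,
    reps: int = 1000,
    tolerance: float = 0.10,
    seed: int | None = None,
) -> StabilizationCurve:
    """Find the sample size at which variance estimates stabilize.

    For each n in ``n_grid``, ``reps`` normal samples of size n are drawn and
    the SD of the sample-variance estimator recorded. Stabilization is the
    smallest n whose spread, relative to the true variance sd^2, is below
    ``tolerance``.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    n_grid = sorted(int(n) for n in n_grid)
    if not n_grid:
        raise ValueError("empty n grid")
    if n_grid[0] < 2:
        raise ValueError("all sample sizes must be >= 2")
    rng = np.random.default_rng(seed)
    true_var = sd**2
    rows = []
    stab_n = None
    for n in n_grid:
        samples = rng.normal(mean, sd, size=(reps, n))
        variances = samples.var(axis=1, ddof=1)
        spread = float(variances.std(ddof=1))
        rel = spread / true_var
        rows.append(
            {
                "n": n,
                "spread": spread,
                "analytic_spread": true_var * np.sqrt(2.0 / (n - 1)),
                "relative_spread": rel,
            }
        )
        if stab_n is None and rel < tolerance:
            stab_n = n
    return StabilizationCurve(
        table=pd.DataFrame(rows),
        stabilization_n=stab_n,
        tolerance=tolerance,
        replicates=reps,
        seed=seed,
    )
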