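"""Evolvability, integration, and similarity statistics for P matrices.

The random-skewers family (respondability, flexibility, autonomy,
constraints) probes a covariance matrix P with random unit-length selection
gradients beta, uniform on the sphere, and summarizes the response vectors
P @ beta:

* respondability — mean ||P beta||: expected pace of mean change under
  directional selection.
* flexibility — mean cos(beta, P beta): how freely the population tracks
  arbitrary selection directions.
* autonomy — mean of conditional evolvability over evolvability,
  (beta' P^-1 beta)^-1 / (beta' P beta): how independent the response in a
  direction is from variation in other directions.
* constraints — mean |cos(P beta, v1)| with v1 the leading eigenvector: how
  strongly responses are channeled along the matrix's main axis.

Whole-matrix integration is measured on the derived correlation matrix:
mean squared correlation and the relative eigenvalue variance Vrel
(Var(lambda)/(d-1), in [0, 1]). The two are algebraically identical
(tr(C^2) - d = 2 * sum of squared off-diagonal correlations), so they serve
as mutual numerical cross-checks here. PCA similarity compares two matrices'
variance geometry through an eigenvalue-weighted overlap of their principal
components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .pmatrix import PMatrix

__all__ = [
    "SkewerEnsemble",
    "draw_skewers",
    "respondability",
    "flexibility",
    "autonomy",
    "constraints",
    "mean_squared_correlation",
    "integration_vrel",
    "compare_vrel",
    "VrelComparison",
    "pca_similarity",
    "covariance_space_pca",
    "CovariancePCA",
    "trait_coupling_table",
    "matrix_stats_report",
    "statistic_function",
    "SKEWER_STATISTICS",
    "STATISTICS",
]

#: Condition-number threshold above which autonomy refuses to invert P.
CONDITION_LIMIT = 1e12


@dataclass
class SkewerEnsemble:
    """A reproducible ensemble of random unit-length selection gradients.

    Vectors are drawn from a standard multivariate Gaussian and normalized to
    unit length, i.e. uniform on the (d-1)-sphere.
    """

    vectors: np.ndarray  # (count, d), rows unit length
    seed: int | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("skewer vectors must be unit length (tolerance 1e-12)")

    @property
    def count(self) -> int:
        return self.vectors.shape[0]

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]


def draw_skewers(d: int, count: int = 10_000, seed: int | None = None) -> SkewerEnsemble:
    """Draw ``count`` random selection gradients uniform on the unit sphere in R^d."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((count, d))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return SkewerEnsemble(vectors=v, seed=seed)


def _cov(P) -> np.ndarray:
    m = P.matrix if isinstance(P, PMatrix) else np.asarray(P, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    return m


def _corr(P) -> np.ndarray:
    if isinstance(P, PMatrix):
        return P.correlation()
    m = _cov(P)
    v = np.diag(m)
    if (v <= 0).any():
        bad = np.flatnonzero(v <= 0).tolist()
        raise ValueError(f"zero-variance trait index(es), correlation undefined: {bad}")
    s = 1.0 / np.sqrt(v)
    c = m * np.outer(s, s)
    np.fill_diagonal(c, 1.0)
    return c


def _responses(P, skewers: SkewerEnsemble) -> np.ndarray:
    m = _cov(P)
    if skewers.dimension != m.shape[0]:
        raise ValueError(
            f"skewer dimension {skewers.dimension} != matrix dimension {m.shape[0]}"
        )
    return skewers.vectors @ m


def respondability(P, skewers: SkewerEnsemble) -> float:
    """Mean response magnitude ||P beta|| over random selection gradients."""
    return float(np.linalg.norm(_responses(P, skewers), axis=1).mean())


def flexibility(P, skewers: SkewerEnsemble) -> float:
    """Mean cosine between selection gradients and their responses.

    Skewers whose response is numerically zero (beta in the null space of a
    rank-deficient P) are skipped; if more than 10% are skipped a warning is
    issued.
    """
    r = _responses(P, skewers)
    norms = np.linalg.norm(r, axis=1)
    scale = np.abs(_cov(P)).max() or 1.0
    ok = norms > 1e-14 * scale
    _warn_skipped(ok, "flexibility")
    cosines = np.einsum("ij,ij->i", skewers.vectors[ok], r[ok]) / norms[ok]
    return float(cosines.mean())


def autonomy(P, skewers: SkewerEnsemble, ridge: float | None = None) -> float:
    """Mean conditional evolvability over evolvability (Hansen-Houle autonomy).

    Requires an invertible P. If the condition number exceeds
    ``CONDITION_LIMIT`` the call fails unless ``ridge`` is given, in which
    case ``ridge * mean(diag(P))`` is added to the diagonal first (matrix
    "bending"; report it whenever used).
    """
    m = _cov(P)
    lam = np.linalg.eigvalsh(m)
    if lam[0] <= 0 or lam[-1] / lam[0] > CONDITION_LIMIT:
        if ridge is None:
            raise ValueError(
                "P is singular or near-singular (condition number > "
                f"{CONDITION_LIMIT:.0e}); pass ridge=... to bend the matrix"
            )
        m = m + ridge * float(np.diag(m).mean()) * np.eye(m.shape[0])
    minv = np.linalg.inv(m)
    b = skewers.vectors
    e = np.einsum("ij,jk,ik->i", b, m, b)  # evolvability beta' P beta
    c = 1.0 / np.einsum("ij,jk,ik->i", b, minv, b)  # conditional evolvability
    return float((c / e).mean())


def constraints(P, skewers: SkewerEnsemble) -> float:
    """Mean |correlation| between response vectors and P's first principal component.

    The absolute value is used because the sign of an eigenvector is
    arbitrary. Fails if the two leading eigenvalues are tied (PC1 undefined).
    """
    m = _cov(P)
    lam, vec = np.linalg.eigh(m)
    if lam[-1] - lam[-2] <= 1e-12 * max(1.0, lam[-1]):
        raise ValueError("tied leading eigenvalues: first principal component undefined")
    v1 = vec[:, -1]
    r = _responses(P, skewers)
    norms = np.linalg.norm(r, axis=1)
    ok = norms > 1e-14 * max(np.abs(m).max(), 1.0)
    _warn_skipped(ok, "constraints")
    cosines = np.abs(r[ok] @ v1) / norms[ok]
    return float(cosines.mean())


def _warn_skipped(ok: np.ndarray, name: str) -> None:
    skipped = ok.size - int(ok.sum())
    if skipped == ok.size:
        raise ValueError(f"all skewer responses are zero; {name} undefined")
    if skipped > 0.1 * ok.size:
        warnings.warn(
            f"{name}: {skipped}/{ok.size} skewers skipped (zero response)",
            RuntimeWarning,
            stacklevel=3,
        )


def mean_squared_correlation(P) -> float:
    """Mean of squared off-diagonal correlations derived from P."""
    c = _corr(P)
    d = c.shape[0]
    if d < 2:
        raise ValueError("need at least 2 traits")
    return float((np.sum(c * c) - d) / (d * (d - 1)))


def integration_vrel(P, n: int | None = None, corrected: bool = False) -> float:
    """Relative eigenvalue variance of the correlation matrix, in [0, 1].

    Vrel = Var(lambda) / (d - 1) with Var(lambda) = sum (lambda_i - 1)^2 / d
    over correlation-matrix eigenvalues. 0 = independent traits, 1 = a single
    effective dimension.

    With ``corrected=True`` (requires ``n``), the small-sample null
    expectation 1/(n-1) — the Vrel a finite sample of independent traits
    shows on average — is rescaled out:
    (Vrel - 1/(n-1)) / (1 - 1/(n-1)).
    """
    c = _corr(P)
    d = c.shape[0]
    if d < 2:
        raise ValueError("need at least 2 traits")
    lam = np.linalg.eigvalsh(c)
    vrel = float(np.mean((lam - 1.0) ** 2) / (d - 1))
    if corrected:
        if n is None:
            n = P.n if isinstance(P, PMatrix) else None
        if n is None or n <= 3:
            raise ValueError("small-sample correction requires n > 3")
        null = 1.0 / (n - 1)
        vrel = (vrel - null) / (1.0 - null)
    return vrel


@dataclass
class VrelComparison:
    """Two-sample z-test of relative eigenvalue variance between matrices."""

    vrel_a: float
    vrel_b: float
    z_a: float
    z_b: float
    z: float
    p_value: float


def compare_vrel(A: PMatrix, B: PMatrix) -> VrelComparison:
    """Compare integration (Vrel) between two matrices by a two-sample z-test.

    Each Vrel is mapped to a Fisher-type effect size z = atanh(sqrt(Vrel))
    with sampling variance 1/(n - 2); the standardized difference is referred
    to the normal distribution (two-sided).
    """
    for M in (A, B):
        if M.n <= 3:
            raise ValueError("compare_vrel requires n > 3 in both groups")
    va, vb = integration_vrel(A), integration_vrel(B)
    za = float(np.arctanh(min(np.sqrt(va), 1 - 1e-15)))
    zb = float(np.arctanh(min(np.sqrt(vb), 1 - 1e-15)))
    se = np.sqrt(1.0 / (A.n - 2) + 1.0 / (B.n - 2))
    z = (za - zb) / se
    p = 2.0 * _stats.norm.sf(abs(z))
    return VrelComparison(vrel_a=va, vrel_b=vb, z_a=za, z_b=zb, z=float(z), p_value=float(p))


def pca_similarity(A: PMatrix | np.ndarray, B: PMatrix | np.ndarray) -> float:
    """Eigenvalue-weighted principal-component overlap of two matrices, in [0, 1].

    S(A, B) = sum_ij lam_i^A lam_j^B (v_i^A . v_j^B)^2 / sum_i lam_i^A lam_i^B
    with eigenvalues sorted descending and clipped at zero. The normalizer is
    pinned by two constraints: S(A, A) = 1 for any PSD A, and S = 0 for
    matrices with disjoint eigenspaces.
    """
    if isinstance(A, PMatrix) and isinstance(B, PMatrix):
        if A.trait_names != B.trait_names:
            raise ValueError("trait sets/order differ between matrices")
    ma, mb = _cov(A), _cov(B)
    if ma.shape != mb.shape:
        raise ValueError(f"matrix dimensions differ: {ma.shape} vs {mb.shape}")
    la, va = np.linalg.eigh(ma)
    lb, vb = np.linalg.eigh(mb)
    la, va = np.clip(la[::-1], 0, None), va[:, ::-1]
    lb, vb = np.clip(lb[::-1], 0, None), vb[:, ::-1]
    overlap = (va.T @ vb) ** 2
    num = la @ overlap @ lb
    denom = float(la @ lb)
    if denom == 0:
        raise ValueError("zero matrices: PCA similarity undefined")
    return float(num / denom)


def _vech_index(d: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(d)
    return iu


def _vech(m: np.ndarray) -> np.ndarray:
    """Unique entries of a symmetric matrix (upper triangle incl. diagonal)."""
    return m[np.triu_indices(m.shape[0])]


@dataclass
class CovariancePCA:
    """Covariance-based PCA of a set of vectorized P matrices.

    ``scores`` has one row per matrix; ``explained`` the percent variance per
    axis; ``loading_correlations`` the correlation of each variance/covariance
    entry with each axis; ``contributions`` the squared-score share (%) of
    each matrix on each axis.
    """

    scores: pd.DataFrame
    explained: pd.Series
    loading_correlations: pd.DataFrame
    contributions: pd.DataFrame
    components: np.ndarray
    mean: np.ndarray
    feature_names: list[str]

    def reconstruct(self) -> np.ndarray:
        """Rebuild the matrix-by-entry table from all PCs (round-trip check)."""
        return self.scores.to_numpy() @ self.components + self.mean


def covariance_space_pca(matrices: Iterable[PMatrix]) -> CovariancePCA:
    """PCA of P matrices in covariance space.

    Each matrix is vectorized to its d(d+1)/2 unique variance and covariance
    entries (covariances counted once); the matrix-by-entry table is centered
    (covariance-based PCA, no scaling) and decomposed by SVD.
    """
    matrices = list(matrices)
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    names = matrices[0].trait_names
    for m in matrices[1:]:
        if m.trait_names != names:
            raise ValueError("all matrices must share the same trait set and order")
    d = len(names)
    iu = np.triu_indices(d)
    feature_names = [
        f"var({names[i]})" if i == j else f"cov({names[i]},{names[j]})"
        for i, j in zip(*iu)
    ]
    x = np.vstack([m.matrix[iu] for m in matrices])
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = u * s
    var = s**2 / max(len(matrices) - 1, 1)
    total = var.sum()
    explained = 100 * var / total if total > 0 else np.zeros_like(var)
    axes = [f"PC{i + 1}" for i in range(len(s))]
    labels = [m.group_label or f"matrix{i + 1}" for i, m in enumerate(matrices)]

    # loading correlations: correlation of each feature with each score axis
    loadcorr = np.full((x.shape[1], len(s)), np.nan)
    fsd = xc.std(axis=0, ddof=1)
    ssd = scores.std(axis=0, ddof=1)
    for k in range(len(s)):
        if ssd[k] > 0:
            ok = fsd > 0
            loadcorr[ok, k] = (xc[:, ok].T @ scores[:, k]) / (
                (len(matrices) - 1) * fsd[ok] * ssd[k]
            )

    sq = scores**2
    denom = sq.sum(axis=0)
    contrib = np.divide(100 * sq, denom, out=np.zeros_like(sq), where=denom > 0)
    return CovariancePCA(
        scores=pd.DataFrame(scores, index=labels, columns=axes),
        explained=pd.Series(explained, index=axes, name="pct_variance"),
        loading_correlations=pd.DataFrame(loadcorr, index=feature_names, columns=axes),
        contributions=pd.DataFrame(contrib, index=labels, columns=axes),
        components=vt,
        mean=mean,
        feature_names=feature_names,
    )


def trait_coupling_table(P: PMatrix) -> pd.DataFrame:
    """Per-pair regression coefficients and squared correlations from P.

    For every ordered trait pair, b(A -> B) = cov(A, B) / var(A) is the
    expected change in B per unit increase in A; r^2(A, B) =
    cov^2 / (var(A) var(B)) is the (symmetric) strength of association.
    Pairs involving a zero-variance trait are flagged undefined (NaN).
    """
    m, names = _cov(P), P.trait_names if isinstance(P, PMatrix) else None
    if names is None:
        names = [f"t{i}" for i in range(m.shape[0])]
    v = np.diag(m)
    rows = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            defined = v[i] > 0 and v[j] > 0
            rows.append(
                {
                    "trait_a": a,
                    "trait_b": b,
                    "covariance": m[i, j],
                    "b_a_to_b": m[i, j] / v[i] if v[i] > 0 else np.nan,
                    "r2": m[i, j] ** 2 / (v[i] * v[j]) if defined else np.nan,
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)


#: Statistics that require a skewer ensemble.
SKEWER_STATISTICS = {
    "respondability": respondability,
    "flexibility": flexibility,
    "autonomy": autonomy,
    "constraints": constraints,
}

#: Statistics computed from the matrix alone.
_SCALAR_STATISTICS = {
    "mean_squared_correlation": mean_squared_correlation,
    "integration_vrel": integration_vrel,
    "total_variance": lambda P: float(np.trace(_cov(P))),
}

STATISTICS = tuple(SKEWER_STATISTICS) + tuple(_SCALAR_STATISTICS)


def statistic_function(name: str, skewers: SkewerEnsemble | None = None, seed=None):
    """Resolve a statistic name to a ``PMatrix -> float`` callable.

    Skewer statistics are bound to ``skewers`` (drawn lazily at the matrix's
    dimension, from ``seed``, on first call if not supplied) so repeated
    evaluations — e.g. across bootstrap replicates — share one ensemble.
    """
    if name in _SCALAR_STATISTICS:
        return _SCALAR_STATISTICS[name]
    if name not in SKEWER_STATISTICS:
        raise ValueError(f"unknown statistic {name!r}; known: {sorted(STATISTICS)}")
    base = SKEWER_STATISTICS[name]
    state = {"skewers": skewers}

    def wrapped(P, _base=base, _state=state):
        if _state["skewers"] is None:
            _state["skewers"] = draw_skewers(_cov(P).shape[0], seed=seed)
        return _base(P, _state["skewers"])

    wrapped.__name__ = name
    return wrapped


def matrix_stats_report(
    P: PMatrix, skewers: SkewerEnsemble | None = None, seed: int | None = None
) -> dict[str, float]:
    """Compute the full statistic suite for one matrix.

    Returns respondability, flexibility, autonomy, constraints, mean squared
    correlation, and integration (Vrel) as a dict.
    """
    if skewers is None:
        skewers = draw_skewers(P.d, seed=seed)
    return {
        "respondability": respondability(P, skewers),
        "flexibility": flexibility(P, skewers),
        "autonomy": autonomy(P, skewers),
        "constraints": constraints(P, skewers),
        "mean_squared_correlation": mean_squared_correlation(P),
        "integration_vrel": integration_vrel(P),
    }
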