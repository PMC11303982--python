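import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_psd(d: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """Random positive-definite covariance matrix (Wishart-style, full rank)."""
    a = rng.standard_normal((d, d + 2))
    m = a @ a.T / (d + 2) * scale
    return (m + m.T) / 2


def residual_frame(x: np.ndarray, group: str = "g", trait_prefix: str = "t") -> pd.DataFrame:
    """Wrap an (n, d) residual array as a minimal trait table."""
    n, d = x.shape
    df = pd.DataFrame(
        {
            "individual_id": [f"{group}-{i}" for i in range(n)],
            "population": "pop",
            "species": "generalist",
            "group": group,
            "standard_length": 35.0,
        }
    )
    for j in range(d):
        df[f"{trait_prefix}{j + 1}"] = x[:, j]
    return df


def naive_skewer_stats(P: np.ndarray, count: int, seed: int) -> dict:
    """Independent brute-force implementation of all four skewer statistics.

    Uses the legacy RandomState generator (a different RNG stream from the
    library's PCG64) and explicit per-skewer loops; returns the mean and
    per-skewer standard error of each statistic.
    """
    rng = np.random.RandomState(seed)
    d = P.shape[0]
    pinv = np.linalg.inv(P)
    lam, vec = np.linalg.eigh(P)
    v1 = vec[:, -1]
    resp, flex, auto, cons = [], [], [], []
    for _ in range(count):
        b = rng.normal(size=d)
        b = b / np.sqrt(np.sum(b * b))
        r = P.dot(b)
        nr = np.sqrt(np.sum(r * r))
        resp.append(nr)
        flex.append(np.dot(b, r) / nr)
        e = np.dot(b, P.dot(b))
        c = 1.0 / np.dot(b, pinv.dot(b))
        auto.append(c / e)
        cons.append(abs(np.dot(r, v1)) / nr)
    out = {}
    for name, vals in (
        ("respondability", resp),
        ("flexibility", flex),
        ("autonomy", auto),
        ("constraints", cons),
    ):
        vals = np.asarray(vals)
        out[name] = (vals.mean(), vals.std(ddof=1) / np.sqrt(count))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240807)
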