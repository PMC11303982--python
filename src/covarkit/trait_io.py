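"""Trait-table I/O, landmark-to-distance conversion, and allometric size standardization.

The measurement pipeline this module supports starts from 2-D landmark
coordinates digitized on lateral photographs of cleared-and-stained fish,
converts named landmark pairs to linear distances in mm, and removes the
allometric effect of body size by regressing each trait on the natural log of
standard length (SL) and keeping the residuals. All downstream covariance
analyses operate on those residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

#: Metadata columns every trait table must carry; every other numeric column
#: is treated as a trait measurement.
META_COLUMNS = ["individual_id", "population", "species", "group", "standard_length"]

LANDMARK_COLUMNS = ["individual_id", "landmark", "x", "y"]


class TraitTableError(ValueError):
    """Raised when a trait or landmark table violates its contract."""


def trait_columns(table: pd.DataFrame) -> list[str]:
    """Return the trait (non-metadata) columns of a trait table, in order.

    Non-numeric extras (e.g. a ``generation`` label on cross tables) are not
    traits and are excluded.
    """
    return [
        c
        for c in table.columns
        if c not in META_COLUMNS
        and c != "generation"
        and pd.api.types.is_numeric_dtype(table[c])
    ]


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a trait table against its invariants and return it.

    Checks: required metadata columns present, no duplicated individual ids,
    strictly positive standard length, numeric trait columns.
    """
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise TraitTableError(f"trait table missing required columns: {missing}")
    dup = table["individual_id"][table["individual_id"].duplicated()]
    if len(dup):
        raise TraitTableError(f"duplicated individual_id values: {sorted(set(dup))}")
    sl = pd.to_numeric(table["standard_length"], errors="coerce")
    if sl.isna().any() or (sl <= 0).any():
        bad = table.loc[sl.isna() | (sl <= 0), "individual_id"].tolist()
        raise TraitTableError(f"standard_length must be > 0 (individuals {bad})")
    traits = trait_columns(table)
    if not traits:
        raise TraitTableError("trait table contains no trait columns")
    for t in traits:
        if not pd.api.types.is_numeric_dtype(table[t]):
            # allow NaN-flagged missingness, but the column must be numeric
            try:
                table[t] = pd.to_numeric(table[t])
            except (TypeError, ValueError) as exc:
                raise TraitTableError(f"trait column {t!r} is not numeric") from exc
    return table


def read_trait_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a CSV/TSV trait table.

    The delimiter is sniffed from the extension unless ``sep`` is given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    table = pd.read_csv(path, sep=sep)
    return validate_trait_table(table)


def write_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_landmark_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format landmark table (individual_id, landmark, x, y[, scale])."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    lm = pd.read_csv(path, sep=sep)
    missing = [c for c in LANDMARK_COLUMNS if c not in lm.columns]
    if missing:
        raise TraitTableError(f"landmark table missing columns: {missing}")
    if not np.isfinite(lm[["x", "y"]].to_numpy(dtype=float)).all():
        raise TraitTableError("landmark coordinates must be finite")
    return lm


def landmarks_to_distances(
    landmarks: pd.DataFrame,
    pairs: dict[str, tuple[str, str]],
    scale: float | None = None,
) -> pd.DataFrame:
    """Convert landmark coordinates to linear trait distances in mm.

    Parameters
    ----------
    landmarks
        Long-format table with columns ``individual_id, landmark, x, y`` and
        optionally a per-row ``scale`` column (mm per pixel).
    pairs
        Mapping of trait name -> (landmark A, landmark B). Each trait is the
        Euclidean distance between the pair, multiplied by the scale factor.
    scale
        Global mm-per-pixel factor. Required unless the table has a ``scale``
        column; must be > 0.

    Returns
    -------
    DataFrame with one row per individual: ``individual_id`` plus one column
    per trait (mm).
    """
    if scale is None and "scale" not in landmarks.columns:
        raise TraitTableError("no scale factor: pass scale= or provide a 'scale' column")
    if scale is not None and scale <= 0:
        raise TraitTableError(f"scale must be > 0, got {scale}")

    coords = landmarks.set_index(["individual_id", "landmark"])[["x", "y"]]
    if coords.index.duplicated().any():
        raise TraitTableError("duplicate (individual, landmark) coordinate rows")
    individuals = landmarks["individual_id"].drop_duplicates().tolist()
    if "scale" in landmarks.columns and scale is None:
        per_ind_scale = landmarks.groupby("individual_id")["scale"].first()
        if (per_ind_scale <= 0).any():
            raise TraitTableError("scale must be > 0 for every individual")
    else:
        per_ind_scale = pd.Series(scale, index=individuals)

    rows = []
    for ind in individuals:
        row: dict[str, object] = {"individual_id": ind}
        for trait, (a, b) in pairs.items():
            for lm in (a, b):
                if (ind, lm) not in coords.index:
                    raise TraitTableError(
                        f"individual {ind!r} is missing landmark {lm!r} "
                        f"(needed for trait {trait!r})"
                    )
            xa, ya = coords.loc[(ind, a)]
            xb, yb = coords.loc[(ind, b)]
            row[trait] = math.hypot(xa - xb, ya - yb) * per_ind_scale[ind]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StandardizationResult:
    """Size-standardized residual trait table plus fitted allometric models.

    Attributes
    ----------
    table
        Copy of the input table with trait columns replaced by residuals of
        the per-trait OLS fit on log standard length. Rows missing a trait
        keep NaN there (never imputed).
    models
        One row per fitted model: trait, scope, group, intercept, slope, n.
    scope
        ``"pooled"`` (one model per trait over all rows) or ``"per-group"``.
    """

    table: pd.DataFrame
    models: pd.DataFrame
    scope: str = "pooled"

    def write(self, residuals_path, models_path) -> None:
        self.table.to_csv(residuals_path, index=False)
        self.models.to_csv(models_path, index=False)


def _fit_one(trait_vals: np.ndarray, log_sl: np.ndarray, label: str):
    ok = np.isfinite(trait_vals) & np.isfinite(log_sl)
    n = int(ok.sum())
    if n < 3:
        raise TraitTableError(f"fewer than 3 usable rows to fit model for {label} (n={n})")
    x, y = log_sl[ok], trait_vals[ok]
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise TraitTableError(f"zero variance in log standard length for {label}; slope undefined")
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
    else:
        fit = _stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    resid = np.full_like(trait_vals, np.nan, dtype=float)
    resid[ok] = y - (intercept + slope * x)
    return resid, intercept, slope, n


def standardize_traits(
    table: pd.DataFrame,
    scope: str = "pooled",
    group_col: str = "group",
) -> StandardizationResult:
    """Remove allometric size effects by OLS regression on log standard length.

    For each trait an ordinary least-squares model ``trait ~ ln(SL)`` is fit
    over the chosen scope and the residuals are returned in place of the raw
    measurements. Natural log is used throughout; the base only rescales the
    slope and leaves residuals unchanged.

    Parameters
    ----------
    scope
        ``"pooled"``: one model per trait across all individuals (a common
        allometric baseline, required for between-group mean comparisons).
        ``"per-group"``: one model per trait within each level of
        ``group_col``.
    """
    if scope not in ("pooled", "per-group"):
        raise TraitTableError(f"unknown standardization scope {scope!r}")
    validate_trait_table(table)
    out = table.copy()
    log_sl = np.log(table["standard_length"].to_numpy(dtype=float))
    traits = trait_columns(table)
    model_rows = []
    if scope == "pooled":
        for t in traits:
            resid, b0, b1, n = _fit_one(out[t].to_numpy(dtype=float), log_sl, f"trait {t!r}")
            out[t] = resid
            model_rows.append(
                {"trait": t, "scope": scope, "group": "(all)", "intercept": b0, "slope": b1, "n": n}
            )
    else:
        for g, idx in table.groupby(group_col, sort=False).groups.items():
            loc = table.index.get_indexer(idx)
            for t in traits:
                resid, b0, b1, n = _fit_one(
                    table[t].to_numpy(dtype=float)[loc], log_sl[loc], f"trait {t!r} in group {g!r}"
                )
                out.loc[idx, t] = resid
                model_rows.append(
                    {"trait": t, "scope": scope, "group": g, "intercept": b0, "slope": b1, "n": n}
                )
    return StandardizationResult(table=out, models=pd.DataFrame(model_rows), scope=scope)
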