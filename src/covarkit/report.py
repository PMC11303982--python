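"""End-to-end analysis runs: standardize -> P matrices -> statistics -> reports.

A single flat config drives the whole pipeline. Every source of randomness
is seeded from one root seed through named substreams, and every output
directory carries a ``run_info.json`` with the seed and a hash of the
config, so identical config + seed reproduce identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import matrix_stats
from .hybrid_null import build_additive_null, test_mean_deviation, test_variance_deviation
from .pmatrix import bootstrap_statistic, compare_groups, estimate_pmatrix
from .trait_io import read_trait_table, standardize_traits, trait_columns

__all__ = ["RunConfig", "CrossConfig", "run_group_comparison", "run_hybrid_analysis"]

#: Statistics bootstrapped and compared in a group run.
REPORT_STATISTICS = [
    "respondability",
    "flexibility",
    "autonomy",
    "constraints",
    "mean_squared_correlation",
    "integration_vrel",
]


class ConfigError(ValueError):
    """Raised when a run config fails validation."""


@dataclass
class CrossConfig:
    label: str
    f2_file: str
    parents_file: str | None = None
    n_loci: int = 1

    _KEYS = {"label", "f2_file", "parents_file", "n_loci"}


@dataclass
class RunConfig:
    """Validated settings for a full analysis run."""

    input: str | None = None
    output_dir: str = "covarkit-out"
    standardize: str = "pooled"  # pooled | per-group | none
    group_column: str = "group"
    groups: list[str] | None = None
    iterations: int = 1000
    skewers: int = 10_000
    ci: float = 0.95
    seed: int = 0
    ddof: int = 1
    ridge: float | None = None
    crosses: list[CrossConfig] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        raw = dict(raw)
        crosses = []
        for c in raw.pop("crosses", []) or []:
            bad = set(c) - CrossConfig._KEYS
            if bad:
                raise ConfigError(f"unknown cross config key(s): {sorted(bad)}")
            crosses.append(CrossConfig(**c))
        cfg = cls(crosses=crosses, **raw)
        if cfg.standardize not in ("pooled", "per-group", "none"):
            raise ConfigError(f"standardize must be pooled|per-group|none, got {cfg.standardize!r}")
        if cfg.iterations < 2:
            raise ConfigError("iterations must be >= 2")
        if not 0 < cfg.ci < 1:
            raise ConfigError("ci must be in (0, 1)")
        if cfg.skewers < 1:
            raise ConfigError("skewers must be >= 1")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _substream_seeds(root_seed: int, names: list[str]) -> dict[str, np.random.SeedSequence]:
    """Named, order-independent substreams derived from the root seed."""
    out = {}
    for name in names:
        tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
        out[name] = np.random.SeedSequence([root_seed, tag])
    return out


def _write_run_info(outdir: Path, config: RunConfig, stages: dict[str, float]) -> None:
    info = {"seed": config.seed, "config_hash": config.config_hash()}
    (outdir / "run_info.json").write_text(json.dumps(info, indent=2) + "\n")
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"seed: {config.seed}\nconfig_hash: {config.config_hash()}\n")
        for stage, seconds in stages.items():
            fh.write(f"{stage}: {seconds:.2f}s\n")


def _prepare_residuals(config: RunConfig, table: pd.DataFrame | None, outdir: Path):
    if table is None:
        if config.input is None:
            raise ConfigError("no input table: set 'input' in the config")
        table = read_trait_table(config.input)
    if config.standardize != "none":
        std = standardize_traits(table, scope=config.standardize, group_col=config.group_column)
        std.table.to_csv(outdir / "residuals.csv", index=False)
        std.models.to_csv(outdir / "standardization_models.csv", index=False)
        return std.table
    return table


def run_group_comparison(config: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Run the wild-group comparison pipeline and write its report bundle.

    Writes, under ``config.output_dir``: one P-matrix CSV per group, a stats
    report with bootstrap CIs, a pairwise difference matrix with significance
    flags, Vrel z-test comparisons, covariance-space PCA scores/loadings, and
    per-group trait-coupling tables.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    t0 = time.perf_counter()
    residuals = _prepare_residuals(config, table, outdir)
    stages["standardize"] = time.perf_counter() - t0

    groups = config.groups or sorted(residuals[config.group_column].dropna().unique())
    if len(groups) < 2:
        raise ConfigError(f"need >= 2 groups, found {groups}")
    traits = trait_columns(residuals)
    seeds = _substream_seeds(config.seed, ["skewers", "bootstrap", "compare"])
    skewers = matrix_stats.draw_skewers(len(traits), config.skewers, seeds["skewers"])

    t0 = time.perf_counter()
    pmatrices = {}
    for g in groups:
        P = estimate_pmatrix(residuals, g, config.group_column, traits, config.ddof)
        pmatrices[g] = P
        P.to_csv(outdir / f"pmatrix_{_slug(g)}.csv")
        matrix_stats.trait_coupling_table(P).to_csv(
            outdir / f"coupling_{_slug(g)}.csv", index=False
        )
    stages["pmatrices"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stat_rows = []
    boot_children = seeds["bootstrap"].spawn(len(groups) * len(REPORT_STATISTICS))
    for i, g in enumerate(groups):
        for j, stat in enumerate(REPORT_STATISTICS):
            res = bootstrap_statistic(
                residuals,
                stat,
                group=g,
                group_col=config.group_column,
                iterations=config.iterations,
                ci=config.ci,
                seed=boot_children[i * len(REPORT_STATISTICS) + j],
                traits=traits,
                ddof=config.ddof,
                skewers=skewers if stat in matrix_stats.SKEWER_STATISTICS else None,
            )
            stat_rows.append(
                {
                    "group": g,
                    "statistic": stat,
                    "estimate": res.point,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "skewers": config.skewers,
                    "seed": config.seed,
                }
            )
    stats_report = pd.DataFrame(stat_rows)
    stats_report.to_csv(outdir / "stats_report.csv", index=False)
    stages["bootstrap_stats"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    comp_rows = []
    pairs = list(combinations(groups, 2))
    comp_children = seeds["compare"].spawn(len(pairs) * len(REPORT_STATISTICS))
    for pi, (a, b) in enumerate(pairs):
        for j, stat in enumerate(REPORT_STATISTICS):
            cmp_res = compare_groups(
                residuals,
                a,
                b,
                stat,
                group_col=config.group_column,
                iterations=config.iterations,
                ci=config.ci,
                seed=comp_children[pi * len(REPORT_STATISTICS) + j],
                traits=traits,
                ddof=config.ddof,
                skewers=skewers if stat in matrix_stats.SKEWER_STATISTICS else None,
            )
            comp_rows.append(
                {
                    "statistic": stat,
                    "group_a": a,
                    "group_b": b,
                    "estimate_a": cmp_res.point_a,
                    "estimate_b": cmp_res.point_b,
                    "difference": cmp_res.difference,
                    "ci_low": cmp_res.ci_low,
                    "ci_high": cmp_res.ci_high,
                    "significant": cmp_res.significant,
                }
            )
        sim = matrix_stats.pca_similarity(pmatrices[a], pmatrices[b])
        comp_rows.append(
            {
                "statistic": "pca_similarity",
                "group_a": a,
                "group_b": b,
                "estimate_a": 1.0,
                "estimate_b": 1.0,
                "difference": sim,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "significant": np.nan,
            }
        )
    comparisons = pd.DataFrame(comp_rows)
    comparisons.to_csv(outdir / "comparisons.csv", index=False)

    vrel_rows = []
    for a, b in pairs:
        vc = matrix_stats.compare_vrel(pmatrices[a], pmatrices[b])
        vrel_rows.append(
            {
                "group_a": a,
                "group_b": b,
                "vrel_a": vc.vrel_a,
                "vrel_b": vc.vrel_b,
                "z": vc.z,
                "p_value": vc.p_value,
            }
        )
    vrel_df = pd.DataFrame(vrel_rows)
    vrel_df.to_csv(outdir / "vrel_comparisons.csv", index=False)
    stages["comparisons"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pca = matrix_stats.covariance_space_pca([pmatrices[g] for g in groups])
    pca.scores.to_csv(outdir / "covariance_pca_scores.csv")
    pca.explained.to_csv(outdir / "covariance_pca_explained.csv")
    pca.loading_correlations.to_csv(outdir / "covariance_pca_loadings.csv")
    pca.contributions.to_csv(outdir / "covariance_pca_contributions.csv")
    stages["covariance_pca"] = time.perf_counter() - t0

    _write_run_info(outdir, config, stages)
    return {
        "pmatrices": pmatrices,
        "stats_report": stats_report,
        "comparisons": comparisons,
        "vrel_comparisons": vrel_df,
        "covariance_pca": pca,
    }


def run_hybrid_analysis(config: RunConfig, tables: dict[str, pd.DataFrame] | None = None) -> dict:
    """Run the F2 hybrid pipeline for each configured cross.

    Per cross: additive-null table from the F0 parents, mean-deviation report,
    variance-deviation test, P matrix and coupling table. With two or more
    crosses, cross-to-cross PCA similarity and Vrel comparisons are added.
    """
    if not config.crosses:
        raise ConfigError("no crosses configured")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    seeds = _substream_seeds(config.seed, ["hybrid"])
    children = seeds["hybrid"].spawn(len(config.crosses))

    results = {}
    pmatrices = {}
    t0 = time.perf_counter()
    for child, cross in zip(children, config.crosses):
        if tables and cross.label in tables:
            table = tables[cross.label]
        else:
            table = read_trait_table(cross.f2_file)
        if "generation" in table.columns:
            f2 = table[table["generation"] == "F2"]
        else:
            f2 = table[table["species"] == "F2-hybrid"]
        if cross.parents_file:
            parents = pd.read_csv(cross.parents_file)
        elif "generation" in table.columns:
            parents = table[table["generation"] == "F0"]
        else:
            raise ConfigError(
                f"cross {cross.label!r}: no parents_file and no 'generation' column "
                "to identify F0 rows"
            )
        if len(parents) != 2:
            raise ConfigError(
                f"cross {cross.label!r}: need exactly 2 F0 parental rows, got {len(parents)}"
            )
        null = build_additive_null(
            parents, n_f2=len(f2), n_loci=cross.n_loci, cross_label=cross.label
        )
        mean_dev = test_mean_deviation(
            f2, null, iterations=config.iterations, ci=config.ci, seed=child
        )
        var_dev = test_variance_deviation(f2, null)
        P = estimate_pmatrix(f2, group=None, traits=null.traits, ddof=config.ddof)
        P.group_label = cross.label
        pmatrices[cross.label] = P

        slug = _slug(cross.label)
        null.as_frame().to_csv(outdir / f"additive_null_{slug}.csv", index=False)
        report = mean_dev.merge(var_dev.table, on="trait")
        report.to_csv(outdir / f"deviation_report_{slug}.csv", index=False)
        P.to_csv(outdir / f"pmatrix_{slug}.csv")
        matrix_stats.trait_coupling_table(P).to_csv(outdir / f"coupling_{slug}.csv", index=False)
        results[cross.label] = {
            "null": null,
            "mean_deviation": mean_dev,
            "variance_deviation": var_dev,
            "pmatrix": P,
        }
    stages["crosses"] = time.perf_counter() - t0

    if len(pmatrices) >= 2:
        rows = []
        for a, b in combinations(pmatrices, 2):
            vc = matrix_stats.compare_vrel(pmatrices[a], pmatrices[b])
            rows.append(
                {
                    "cross_a": a,
                    "cross_b": b,
                    "pca_similarity": matrix_stats.pca_similarity(pmatrices[a], pmatrices[b]),
                    "vrel_a": vc.vrel_a,
                    "vrel_b": vc.vrel_b,
                    "vrel_z": vc.z,
                    "vrel_p": vc.p_value,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "cross_comparisons.csv", index=False)
        results["cross_comparisons"] = pd.DataFrame(rows)

    _write_run_info(outdir, config, stages)
    return results


def _slug(label) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "-" for c in str(label))
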