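"""End-to-end orchestration: simulate/load -> climate deltas -> effect
sizes -> pairwise meta-regressions -> all-subsets selection -> economics
axis -> ancillary regressions -> report bundle.

Everything is driven by a :class:`RunConfig` and a single seed; two runs
with the same config produce identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from . import __version__
from .climate_metrics import (
    METRICS, SCALING, ClimateConfig, collinearity_screen, compute_all_changes,
)
from .effect_sizes import effects_from_measurements, overall_species_change
from .leaf_economics import econ_scores_as_response, horn_parallel, impute_pca, pca
from .meta_regression import fit_meta_regression, intercept_diagnostic
from .model_selection import enumerate_and_fit, importance_table
from .synth import (
    ClimateSimConfig, TraitSimConfig, generate_daily_climate,
    generate_trait_cohorts, sample_species_configs,
)

log = logging.getLogger("ccre")

__all__ = [
    "RunConfig", "simulate_study", "run_pairwise", "run_selection",
    "run_economics", "ancillary_regression", "run_all", "significance_stars",
]

PAIRWISE_MODERATORS = ("mean_temp", "mean_precip")

# Table-legend significance thresholds
_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"))


def significance_stars(p: float) -> str:
    for cut, stars in _STAR_LEVELS:
        if p < cut:
            return stars
    return ""


@dataclass
class RunConfig:
    seed: int = 0
    n_species: int = 32
    alpha: float = 0.05
    analysis_traits: tuple[str, ...] = ("leaf_area", "leaf_thickness")
    econ_traits: dict = field(default_factory=lambda: {
        "sla": "delta_sla", "asat": "delta_asat", "nitrogen": "delta_n"})
    selection_max_terms: int | None = None
    method: str = "REML"
    impute_rank: int = 1
    horn_iterations: int = 500
    scale_columns: bool = False
    out_dir: str | None = None
    climate: ClimateSimConfig = field(default_factory=ClimateSimConfig)
    traits: TraitSimConfig = field(default_factory=TraitSimConfig)
    climate_metrics: ClimateConfig = field(default_factory=ClimateConfig)

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.analysis_traits:
            raise ValueError("trait list must be non-empty")


def simulate_study(config: RunConfig):
    """Generate per-species paired weather, compute the realised climate
    deltas with the metric machinery, then condition trait cohorts on
    those deltas.  Returns (changes, measurements, truth, params)."""
    sim_traits = tuple(dict.fromkeys(
        tuple(config.analysis_traits) + tuple(config.econ_traits)))
    species_cfgs = sample_species_configs(
        config.climate, config.n_species, seed=config.seed)
    rows = {}
    for species, cfg in species_cfgs.items():
        sim = generate_daily_climate(cfg)
        changes = compute_all_changes(
            sim.historic, sim.modern, sim.historic_date, sim.modern_date,
            config.climate_metrics)
        rows[species] = changes.as_series()
    changes_df = pd.DataFrame(rows).T
    changes_df.index.name = "species"

    trait_cfg = dataclasses.replace(
        config.traits, n_species=config.n_species, traits=sim_traits,
        seed=config.seed + 1)
    sim = generate_trait_cohorts(changes_df, trait_cfg)
    return changes_df, sim.measurements, sim.truth, sim.params


def run_pairwise(effects: pd.DataFrame, changes: pd.DataFrame,
                 traits, method: str = "REML", alpha: float = 0.05,
                 moderators=PAIRWISE_MODERATORS) -> pd.DataFrame:
    """Separate single-moderator weighted meta-regressions per trait.

    One row per trait x moderator with slope, Wald inference, pseudo-R2
    and the intercept diagnostic.  Traits with fewer than 3 complete
    species are skipped (logged).
    """
    rows = []
    for trait in traits:
        sub = effects[(effects["trait"] == trait) & effects["yi"].notna()]
        sub = sub.set_index("species")
        for moderator in moderators:
            x = changes[moderator].reindex(sub.index)
            ok = x.notna() & np.isfinite(sub["yi"]) & np.isfinite(sub["vi"])
            k = int(ok.sum())
            if k < 3:
                log.warning("trait %s x %s skipped: only %d species", trait, moderator, k)
                continue
            fit = fit_meta_regression(
                sub.loc[ok, "yi"].to_numpy(), sub.loc[ok, "vi"].to_numpy(),
                x[ok].to_numpy(), method=method, moderator_names=[moderator])
            sig, p_int = intercept_diagnostic(fit, alpha)
            rows.append({
                "trait": trait, "moderator": moderator, "k": k,
                "slope": fit.beta[1], "se": fit.se[1], "p": fit.p[1],
                "pseudo_r2": fit.pseudo_r2, "tau2": fit.tau2,
                "intercept": fit.beta[0], "intercept_p": p_int,
                "intercept_sig": sig,
            })
    return pd.DataFrame(rows)


def run_selection(effects: pd.DataFrame, changes: pd.DataFrame, traits,
                  method: str = "REML", max_terms: int | None = None):
    """Per-trait all-subsets AICc selection over the 12 moderators."""
    results = {}
    for trait in traits:
        sub = effects[(effects["trait"] == trait) & effects["yi"].notna()]
        sub = sub.set_index("species")
        mods = changes.loc[changes.index.intersection(sub.index), list(METRICS)]
        sub = sub.loc[mods.index]
        results[trait] = enumerate_and_fit(
            sub["yi"].to_numpy(), sub["vi"].to_numpy(), mods,
            method=method, max_terms=max_terms)
    imp, best = importance_table(results)
    return results, imp, best


def run_economics(effects: pd.DataFrame, changes: pd.DataFrame,
                  econ_traits: dict, config: RunConfig):
    """Economics-axis chain: change matrix -> imputation -> PCA -> Horn's
    retention -> equal-weight regressions of PC scores on mean climate."""
    cols = {}
    for trait, col in econ_traits.items():
        sub = effects[effects["trait"] == trait].set_index("species")["yi"]
        cols[col] = sub
    M = pd.DataFrame(cols)
    M = M.loc[M.notna().any(axis=1)]
    completed = impute_pca(M, n_comp=config.impute_rank)
    result = pca(completed, scale_columns=config.scale_columns)
    retained = horn_parallel(
        completed, n_iter=config.horn_iterations, seed=config.seed)
    components = tuple(range(1, max(retained, 1) + 1))
    scores = econ_scores_as_response(result, components=components)

    reg_rows = []
    for comp in scores.columns:
        y = scores[comp]
        for moderator in PAIRWISE_MODERATORS:
            x = changes[moderator].reindex(y.index)
            ok = x.notna()
            # component scores carry no sampling variance: equal weights
            fit = fit_meta_regression(
                y[ok].to_numpy(), np.ones(int(ok.sum())), x[ok].to_numpy(),
                method=config.method, moderator_names=[moderator])
            reg_rows.append({
                "component": comp, "moderator": moderator, "k": int(ok.sum()),
                "slope": fit.beta[1], "se": fit.se[1], "p": fit.p[1],
                "pseudo_r2": fit.pseudo_r2,
            })
    return {
        "matrix": M, "completed": completed, "pca": result,
        "retained": retained, "scores": scores,
        "regressions": pd.DataFrame(reg_rows),
        "explained": result.explained,
    }


def ancillary_regression(overall: pd.Series, covariates: pd.DataFrame,
                         categorical=("growth_form",)) -> pd.DataFrame:
    """Unweighted OLS of ln(overall species change) on each covariate
    separately; reports adjusted R2 (may be negative) and the model p."""
    y = np.log(overall.astype(float))
    rows = []
    for cov in covariates.columns:
        df = pd.DataFrame({"y": y, "x": covariates[cov]}).dropna()
        if len(df) < 3:
            log.warning("ancillary covariate %s skipped: %d complete cases", cov, len(df))
            continue
        if np.ptp(df["y"].to_numpy()) == 0.0:
            # degenerate response: no variance to explain
            rows.append({"covariate": cov, "k": len(df), "adj_r2": 0.0, "p": 1.0})
            continue
        formula = "y ~ C(x)" if cov in categorical else "y ~ x"
        fit = smf.ols(formula, data=df).fit()
        rows.append({
            "covariate": cov, "k": int(fit.nobs),
            "adj_r2": fit.rsquared_adj, "p": fit.f_pvalue,
        })
    return pd.DataFrame(rows)


def _default_covariates(species, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed + 99)
    forms = rng.choice(["herb", "shrub", "shrub_tree", "tree"], size=len(species))
    return pd.DataFrame(
        {
            "growth_form": forms,
            "maturity_age": rng.uniform(1.0, 15.0, len(species)).round(2),
            "lifespan": rng.uniform(5.0, 120.0, len(species)).round(1),
            "d_co2": rng.uniform(0.05, 0.09, len(species)).round(5),
        },
        index=species,
    )


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full pipeline on simulated inputs; optionally writes a CSV bundle.

    Returns a dict with every intermediate table plus a manifest of the
    decisions (scalings, extreme-index constants, imputation rank, seeds)
    so a run is fully auditable.
    """
    changes, measurements, truth, params = simulate_study(config)
    corr, corr_flags = collinearity_screen(changes[list(METRICS)])
    effects = effects_from_measurements(measurements)

    pairwise = run_pairwise(
        effects, changes, config.analysis_traits,
        method=config.method, alpha=config.alpha)
    selection, importance, best = run_selection(
        effects, changes, config.analysis_traits,
        method=config.method, max_terms=config.selection_max_terms)
    economics = run_economics(effects, changes, config.econ_traits, config)

    overall = (
        effects[effects["yi"].notna()]
        .groupby("species")["yi"].apply(lambda s: overall_species_change(s.tolist()))
    )
    covariates = _default_covariates(sorted(changes.index), config.seed)
    ancillary = ancillary_regression(
        overall, covariates.loc[overall.index.intersection(covariates.index)])

    model_tables = {
        trait: res.models.assign(
            subset=res.models["subset"].map(lambda s: "+".join(s) if s else "(intercept)"))
        for trait, res in selection.items()
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_species": config.n_species,
        "method": config.method,
        "alpha": config.alpha,
        "scalings": dict(SCALING),
        "climate_constants": dataclasses.asdict(config.climate_metrics),
        "impute_rank": config.impute_rank,
        "pca_scaled": config.scale_columns,
        "horn_retained": int(economics["retained"]),
        "explained_pct": [round(float(e), 6) for e in economics["explained"]],
        "per_trait_k": {t: int(r.k) for t, r in selection.items()},
        "trait_sim": params,
    }

    bundle = {
        "changes": changes, "correlations": corr, "correlation_flags": corr_flags,
        "effects": effects, "truth": truth, "pairwise": pairwise,
        "selection": selection, "importance": importance, "best_models": best,
        "model_tables": model_tables, "economics": economics,
        "overall_change": overall, "ancillary": ancillary, "manifest": manifest,
    }
    if out_dir is None:
        out_dir = config.out_dir
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


_FLOAT_FMT = "%.12g"


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fmt = {"float_format": _FLOAT_FMT}
    bundle["changes"].to_csv(out / "climate_changes.csv", **fmt)
    bundle["correlations"].to_csv(out / "climate_correlations.csv", **fmt)
    bundle["correlation_flags"].to_csv(out / "collinearity_flags.csv", index=False, **fmt)
    bundle["effects"].to_csv(out / "effect_sizes.csv", index=False, **fmt)
    bundle["pairwise"].to_csv(out / "pairwise_regressions.csv", index=False, **fmt)
    bundle["importance"].to_csv(out / "importance_matrix.csv", **fmt)
    best = bundle["best_models"].copy()
    best["in_best"] = best["in_best"].map(lambda s: "+".join(s) if s else "")
    best.to_csv(out / "best_models.csv", **fmt)
    for trait, table in bundle["model_tables"].items():
        table.to_csv(out / f"models_{trait}.csv", index=False, **fmt)
    bundle["economics"]["regressions"].to_csv(
        out / "economics_regressions.csv", index=False, **fmt)
    bundle["economics"]["scores"].to_csv(out / "economics_scores.csv", **fmt)
    bundle["overall_change"].rename("overall_change").to_csv(
        out / "overall_species_change.csv", **fmt)
    bundle["ancillary"].to_csv(out / "ancillary_regressions.csv", index=False, **fmt)
    bundle["truth"].to_csv(out / "simulation_truth.csv", index=False, **fmt)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True, default=str)
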