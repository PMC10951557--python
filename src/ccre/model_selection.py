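"""All-subsets AICc model selection over climate-change moderators.

Every subset of the candidate moderators (including the intercept-only
model) is fitted by :func:`ccre.meta_regression.fit_meta_regression`;
models are ranked by small-sample AIC computed from ML log-likelihoods,
converted to Akaike weights, and summarised as per-moderator importances
(the summed weight of all models containing the moderator) and
zero-substitution model-averaged coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meta_regression import fit_meta_regression

__all__ = ["aicc", "enumerate_and_fit", "importance_table", "ModelSelectionResult", "TABLE_GROUPS"]

_MAX_MODERATORS = 14

# presentation order and grouping of the 12 climate-change moderators
TABLE_GROUPS = (
    ("Mean", ("mean_temp", "mean_precip")),
    ("Variability", ("temp_var", "precip_var")),
    ("Range", ("temp_range", "precip_range")),
    ("Seasonal precip.", ("max_seasonal_precip", "min_seasonal_precip")),
    ("Aridity", ("vpd",)),
    ("Climate extremes", ("max_drought_dur", "max_heatwave_dur", "max_dryspell_dur")),
)


def aicc(loglik: float, n_params: int, k_obs: int) -> float:
    """AIC corrected for small samples.

    ``n_params`` counts the intercept, the moderators and tau2.  Raises
    when the correction denominator ``k_obs - n_params - 1`` is not
    positive (such models are excluded from candidate sets upstream).
    """
    denom = k_obs - n_params - 1
    if denom <= 0:
        raise ValueError(
            f"AICc undefined: k_obs={k_obs} too small for n_params={n_params}"
        )
    return -2.0 * loglik + 2.0 * n_params + 2.0 * n_params * (n_params + 1) / denom


@dataclass
class ModelSelectionResult:
    """Ranked all-subsets fits plus weight-based summaries."""

    models: pd.DataFrame            # subset, n_terms, loglik, aicc, delta, weight
    importance: dict[str, float]
    best: tuple[str, ...]           # moderator subset with minimal AICc
    best_fit: object                # MetaRegressionFit of the best model
    averaged_coefficients: dict[str, float]
    k: int
    moderators: tuple[str, ...] = field(default_factory=tuple)
    excluded: list[dict] = field(default_factory=list)
    dropped_species: list = field(default_factory=list)


def _complete_cases(yi, vi, moderators: pd.DataFrame):
    mask = np.isfinite(np.asarray(yi, float)) & np.isfinite(np.asarray(vi, float))
    mask &= np.isfinite(moderators.to_numpy(dtype=float)).all(axis=1)
    return np.asarray(mask)


def enumerate_and_fit(
    yi,
    vi,
    moderators: pd.DataFrame,
    method: str = "REML",
    max_terms: int | None = None,
) -> ModelSelectionResult:
    """Fit every moderator subset and summarise by Akaike weight.

    Species with a missing effect size or any missing moderator are
    dropped (complete-case analysis) and recorded in ``dropped_species``.
    """
    names = tuple(moderators.columns)
    m = len(names)
    if m > _MAX_MODERATORS:
        raise ValueError(
            f"{m} moderators imply 2^{m} fits; cap with max_terms or reduce the set"
        )
    yi = np.asarray(yi, dtype=float)
    vi = np.asarray(vi, dtype=float)
    mask = _complete_cases(yi, vi, moderators)
    dropped = list(moderators.index[~mask])
    y, v = yi[mask], vi[mask]
    Xall = moderators.to_numpy(dtype=float)[mask]
    k = int(mask.sum())
    if k < 3:
        raise ValueError(f"only {k} complete cases; need at least 3")

    limit = m if max_terms is None else min(max_terms, m)
    rows, fits, excluded = [], {}, []
    for size in range(0, limit + 1):
        for subset in itertools.combinations(range(m), size):
            sub_names = tuple(names[j] for j in subset)
            n_params = 1 + size + 1  # intercept + moderators + tau2
            if k - n_params - 1 <= 0:
                excluded.append({"subset": sub_names, "reason": "aicc denominator <= 0"})
                continue
            X = Xall[:, subset] if size else None
            try:
                fit = fit_meta_regression(
                    y, v, X, method=method, moderator_names=list(sub_names),
                    compute_pseudo_r2=False,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                excluded.append({"subset": sub_names, "reason": str(exc)})
                continue
            if not fit.converged:
                excluded.append({"subset": sub_names, "reason": "non-convergent"})
                continue
            fits[sub_names] = fit
            rows.append(
                {
                    "subset": sub_names,
                    "n_terms": size,
                    "loglik_ml": fit.loglik_ml,
                    "aicc": aicc(fit.loglik_ml, n_params, k),
                }
            )
    if not rows:
        raise ValueError("no candidate model could be fitted")

    table = pd.DataFrame(rows)
    table["delta"] = table["aicc"] - table["aicc"].min()
    rel = np.exp(-0.5 * table["delta"].to_numpy())
    table["weight"] = rel / rel.sum()
    table = table.sort_values("aicc", kind="mergesort").reset_index(drop=True)

    importance = {n: 0.0 for n in names}
    averaged = {n: 0.0 for n in names}  # zero-substitution averaging
    for subset, weight in zip(table["subset"], table["weight"]):
        fit = fits[subset]
        for pos, name in enumerate(subset):
            importance[name] += float(weight)
            averaged[name] += float(weight) * float(fit.beta[1 + pos])

    best = tuple(table.iloc[0]["subset"])
    best_fit = fit_meta_regression(
        y, v, Xall[:, [names.index(n) for n in best]] if best else None,
        method=method, moderator_names=list(best),
    )
    return ModelSelectionResult(
        models=table, importance=importance, best=best, best_fit=best_fit,
        averaged_coefficients=averaged, k=k, moderators=names,
        excluded=excluded, dropped_species=dropped,
    )


def importance_table(results: dict[str, ModelSelectionResult]):
    """Assemble the importance matrix (12 metrics x traits) plus a
    best-model summary row block.

    Returns ``(importance, best)``: the matrix of per-moderator
    importances in the fixed group order, and a per-trait frame with the
    best-model subset, its pseudo-R2 and the intercept-only flag.
    """
    metric_order = [n for _, group in TABLE_GROUPS for n in group]
    imp = pd.DataFrame(index=metric_order, columns=list(results), dtype=float)
    best_rows = {}
    for trait, res in results.items():
        for name in metric_order:
            imp.loc[name, trait] = res.importance.get(name, np.nan)
        best_rows[trait] = {
            "best_model": " + ".join(res.best) if res.best else "Intercept only",
            "pseudo_r2": res.best_fit.pseudo_r2,
            "k": res.k,
            "in_best": res.best,
        }
    return imp, pd.DataFrame(best_rows).T
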