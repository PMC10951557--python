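"""Log-ratio-of-means effect sizes from paired historic/modern cohorts.

For each species x trait the effect size is ``yi = ln(mean_mod / mean_hist)``
with the delta-method sampling variance

    vi = sd_mod^2 / (n_mod * mean_mod^2) + sd_hist^2 / (n_hist * mean_hist^2)

which weights all downstream meta-regressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CohortSummary",
    "EffectSize",
    "summarize_cohort",
    "lnrr",
    "compute_iwue",
    "overall_species_change",
    "effects_from_measurements",
    "effects_from_summaries",
]

HISTORIC = "historic"
MODERN = "modern"


@dataclass(frozen=True)
class CohortSummary:
    species: str
    trait: str
    era: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class EffectSize:
    species: str
    trait: str
    yi: float
    vi: float


class CohortError(ValueError):
    """A cohort cannot contribute an effect size; carries the reason."""


def summarize_cohort(values, species: str = "", trait: str = "", era: str = "") -> CohortSummary:
    """Mean, sample SD (n-1 denominator) and n of one cohort.

    Raises :class:`CohortError` for cohorts with fewer than two finite
    positive values — such species x trait cells are dropped and logged
    by the callers, never silently defaulted.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise CohortError(f"cohort {species}/{trait}/{era}: fewer than 2 values")
    if not np.all(np.isfinite(arr)):
        raise CohortError(f"cohort {species}/{trait}/{era}: non-finite values")
    if np.any(arr <= 0):
        raise CohortError(f"cohort {species}/{trait}/{era}: non-positive values")
    return CohortSummary(
        species=species, trait=trait, era=era,
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size),
    )


def lnrr(hist: CohortSummary, mod: CohortSummary) -> EffectSize:
    """Ratio-of-means effect size with its delta-method variance."""
    if hist.mean <= 0 or mod.mean <= 0:
        raise CohortError(
            f"{hist.species}/{hist.trait}: lnRR needs positive means "
            f"(historic {hist.mean}, modern {mod.mean})"
        )
    if hist.sd < 0 or mod.sd < 0:
        raise CohortError(f"{hist.species}/{hist.trait}: negative sd")
    if hist.n < 2 or mod.n < 2:
        raise CohortError(f"{hist.species}/{hist.trait}: n < 2")
    vi = mod.sd**2 / (mod.n * mod.mean**2) + hist.sd**2 / (hist.n * hist.mean**2)
    if vi <= 0:
        raise CohortError(
            f"{hist.species}/{hist.trait}: zero sampling variance (both sds 0)"
        )
    return EffectSize(
        species=hist.species, trait=hist.trait,
        yi=math.log(mod.mean / hist.mean), vi=float(vi),
    )


def compute_iwue(a_sat, g_s):
    """Intrinsic water-use efficiency per individual: a_sat / g_s.

    Individuals with non-positive stomatal conductance yield NaN (they
    are dropped before cohort summarisation).
    """
    a = np.asarray(a_sat, dtype=float)
    g = np.asarray(g_s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(g > 0, a / np.where(g > 0, g, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def overall_species_change(effects) -> float:
    """|mean of yi across traits| — one magnitude-of-change score per species."""
    ys = [e.yi if isinstance(e, EffectSize) else float(e) for e in effects]
    if not ys:
        raise ValueError("no effect sizes supplied")
    return abs(float(np.mean(ys)))


def _pair_effects(summaries: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (species, trait), grp in summaries.groupby(["species", "trait"], sort=True):
        eras = dict(zip(grp["era"], grp.index))
        row = {"species": species, "trait": trait, "yi": np.nan, "vi": np.nan, "flag": ""}
        if HISTORIC not in eras or MODERN not in eras:
            row["flag"] = "missing era"
        else:
            h = grp.loc[eras[HISTORIC]]
            m = grp.loc[eras[MODERN]]
            try:
                hist = CohortSummary(species, trait, HISTORIC, float(h["mean"]), float(h["sd"]), int(h["n"]))
                mod = CohortSummary(species, trait, MODERN, float(m["mean"]), float(m["sd"]), int(m["n"]))
                es = lnrr(hist, mod)
                row["yi"], row["vi"] = es.yi, es.vi
            except CohortError as exc:
                row["flag"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def effects_from_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Effect sizes from a ``species,era,trait,mean,sd,n`` summary table."""
    required = {"species", "era", "trait", "mean", "sd", "n"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summary table lacks columns: {sorted(missing)}")
    return _pair_effects(summaries)


def effects_from_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """Effect sizes from a tidy ``species,era,trait,value`` table.

    Returns one row per species x trait with ``yi``, ``vi`` and a
    ``flag`` column explaining any unusable cell.
    """
    required = {"species", "era", "trait", "value"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
    rows = []
    for (species, era, trait), grp in measurements.groupby(
        ["species", "era", "trait"], sort=True
    ):
        vals = grp["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals) & (vals > 0)]
        if vals.size < 2:
            rows.append({"species": species, "era": era, "trait": trait,
                         "mean": np.nan, "sd": np.nan, "n": vals.size})
            continue
        s = summarize_cohort(vals, species, trait, era)
        rows.append({"species": species, "era": era, "trait": trait,
                     "mean": s.mean, "sd": s.sd, "n": s.n})
    return _pair_effects(pd.DataFrame(rows).dropna(subset=["mean"]))
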