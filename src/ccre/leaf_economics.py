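"""Leaf-economics change axis: imputation, PCA and component retention.

The three per-species change variables (delta SLA, delta photosynthetic
rate, delta nitrogen) rarely form a complete matrix; missing cells are
filled by iterative low-rank PCA imputation, the completed matrix is
decomposed by column-centred SVD, and Horn's parallel analysis decides
how many components to retain.  Retained component scores are handed to
the meta-regression layer as equal-weight responses (component scores
carry no sampling variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ECON_COLUMNS",
    "PcaResult",
    "impute_pca",
    "pca",
    "horn_parallel",
    "econ_scores_as_response",
]

ECON_COLUMNS = ("delta_sla", "delta_asat", "delta_n")


@dataclass
class PcaResult:
    loadings: pd.DataFrame      # variables x components, orthonormal columns
    scores: pd.DataFrame        # species x components
    explained: np.ndarray       # % of variance per component, sums to 100
    eigenvalues: np.ndarray
    scaled: bool


def _check_matrix(M: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(M).astype(float)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("economics matrix needs at least 2 rows and 2 columns")
    all_missing_rows = df.index[df.isna().all(axis=1)]
    if len(all_missing_rows):
        raise ValueError(f"rows with no observed value: {list(all_missing_rows)}")
    all_missing_cols = df.columns[df.isna().all(axis=0)]
    if len(all_missing_cols):
        raise ValueError(f"columns with no observed value: {list(all_missing_cols)}")
    return df


def impute_pca(M: pd.DataFrame, n_comp: int = 1, max_iter: int = 1000,
               tol: float = 1e-8) -> pd.DataFrame:
    """Iterative-PCA completion of a matrix with missing cells.

    Missing cells start at their column means; each pass centres the
    current matrix, reconstructs it at rank ``n_comp`` and overwrites
    only the missing cells, until the largest change in an imputed cell
    falls below ``tol``.  Observed cells are never altered.  ``n_comp=0``
    degenerates to mean imputation.
    """
    df = _check_matrix(M)
    n, p = df.shape
    if not 0 <= n_comp < min(n, p):
        raise ValueError(f"n_comp must lie in [0, {min(n, p) - 1}]")
    mask = df.isna().to_numpy()
    X = df.to_numpy(dtype=float)
    col_means = np.nanmean(X, axis=0)
    X[mask] = np.take(col_means, np.where(mask)[1])
    if n_comp == 0 or not mask.any():
        return pd.DataFrame(X, index=df.index, columns=df.columns)
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        recon = (U[:, :n_comp] * s[:n_comp]) @ Vt[:n_comp] + mu
        delta = np.max(np.abs(recon[mask] - X[mask]))
        X[mask] = recon[mask]
        if delta < tol:
            break
    return pd.DataFrame(X, index=df.index, columns=df.columns)


def pca(M: pd.DataFrame, scale_columns: bool = False) -> PcaResult:
    """Column-centred (optionally unit-scaled) PCA via SVD.

    Signs are fixed so each loading column's largest-magnitude entry is
    positive; explained percentages sum to 100 over all components.
    """
    df = pd.DataFrame(M).astype(float)
    if df.isna().any().any():
        raise ValueError("PCA input must have no missing cells (impute first)")
    X = df.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale_columns:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = list(df.columns[sd == 0])
            raise ValueError(f"zero-variance columns cannot be scaled: {zero}")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    eig = s**2 / (X.shape[0] - 1)
    explained = 100.0 * eig / eig.sum() if eig.sum() > 0 else np.zeros_like(eig)
    comps = [f"PC{j + 1}" for j in range(len(s))]
    return PcaResult(
        loadings=pd.DataFrame(Vt.T, index=df.columns, columns=comps),
        scores=pd.DataFrame(U * s, index=df.index, columns=comps),
        explained=explained,
        eigenvalues=eig,
        scaled=scale_columns,
    )


def _corr_eigenvalues(X: np.ndarray) -> np.ndarray:
    Xs = X - X.mean(axis=0)
    sd = Xs.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column in parallel analysis input")
    Xs = Xs / sd
    ev = np.linalg.eigvalsh(np.cov(Xs, rowvar=False))
    return np.sort(ev)[::-1]


def horn_parallel(M: pd.DataFrame, n_iter: int = 1000,
                  percentile_rule: str = "mean", seed: int = 0) -> int:
    """Horn's parallel analysis: retained component count.

    Observed correlation-matrix eigenvalues are compared against those of
    ``n_iter`` same-shaped standard-normal matrices.  Under the ``mean``
    rule a component is retained while its adjusted eigenvalue
    (observed - random mean + 1) exceeds 1; under ``p95`` while the
    observed eigenvalue exceeds the random 95th percentile.  Retention is
    contiguous from the first component.
    """
    if percentile_rule not in ("mean", "p95"):
        raise ValueError("percentile_rule must be 'mean' or 'p95'")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    df = _check_matrix(M)
    if df.isna().any().any():
        raise ValueError("parallel analysis input must be complete")
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    obs = _corr_eigenvalues(X)
    rng = np.random.default_rng(seed)
    rand = np.empty((n_iter, p))
    for it in range(n_iter):
        rand[it] = _corr_eigenvalues(rng.normal(size=(n, p)))
    if percentile_rule == "mean":
        threshold_pass = (obs - rand.mean(axis=0) + 1.0) > 1.0
    else:
        threshold_pass = obs > np.percentile(rand, 95.0, axis=0)
    retained = 0
    for ok in threshold_pass:
        if not ok:
            break
        retained += 1
    return retained


def econ_scores_as_response(result: PcaResult, components=(1, 2)) -> pd.DataFrame:
    """Component scores keyed by species, for use as equal-weight
    meta-regression responses (no sampling variance is available)."""
    cols = [f"PC{c}" for c in components]
    missing = [c for c in cols if c not in result.scores.columns]
    if missing:
        raise ValueError(f"components not present: {missing}")
    return result.scores[cols].copy()
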