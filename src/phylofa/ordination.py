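"""Eigen-decomposition PCA on species-mean trait profiles.

The decomposition is of the covariance matrix (divisor n−1) of the species ×
trait matrix of mean logit FA proportions. Individual measurements are
projected with the same center and eigenvectors to expose intraspecific
variation. Axis retention follows the broken-stick null: an axis is kept
while its explained variance fraction exceeds the broken-stick expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signal import holm_adjust

__all__ = [
    "PCAResult",
    "pca_species_means",
    "project",
    "broken_stick",
    "select_axes",
    "correlate_with_axes",
]


@dataclass
class PCAResult:
    """Eigen-PCA of a species × trait matrix.

    ``eigenvectors`` columns are orthonormal loadings with the sign fixed so
    the largest-magnitude loading of each axis is positive; ``species_scores``
    are centered projections of the species means.
    """

    center: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    species_scores: pd.DataFrame
    explained_fraction: np.ndarray
    broken_stick: np.ndarray
    trait_names: list[str] = field(default_factory=list)


def pca_species_means(X: pd.DataFrame) -> PCAResult:
    """Eigen-PCA of the covariance matrix of species-mean traits.

    ``X`` is species × trait with no missing values. Eigenvalues are returned
    in nonincreasing order (clipped at 0); scores are (X − center)·V.
    """
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 species and 2 traits")
    M = X.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("missing values in trait matrix")
    center = M.mean(axis=0)
    S = np.cov(M, rowvar=False, ddof=1)
    if not np.any(S):
        raise ValueError("rank-0 trait matrix (all species identical)")
    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    # sign convention: largest-|loading| entry of each axis positive
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    scores = (M - center) @ V
    p = len(w)
    cols = [f"PC{k + 1}" for k in range(p)]
    return PCAResult(
        center=center,
        eigenvalues=w,
        eigenvectors=V,
        species_scores=pd.DataFrame(scores, index=X.index, columns=cols),
        explained_fraction=w / w.sum(),
        broken_stick=broken_stick(p),
        trait_names=list(X.columns),
    )


def project(result: PCAResult, observations: pd.DataFrame) -> pd.DataFrame:
    """Project measurement-level rows with the species-mean center and eigenvectors."""
    M = observations[result.trait_names].to_numpy(dtype=float)
    scores = (M - result.center) @ result.eigenvectors
    cols = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return pd.DataFrame(scores, index=observations.index, columns=cols)


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick expected variance fractions b_k = (1/p) Σ_{i=k..p} 1/i."""
    if p < 1:
        raise ValueError("p must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def select_axes(result: PCAResult) -> list[int]:
    """Leading run of axes whose explained fraction beats the broken-stick null.

    Returns 1-based axis indices, starting at PC1; stops at the first axis
    that fails.
    """
    kept: list[int] = []
    for k, (f, b) in enumerate(zip(result.explained_fraction, result.broken_stick), start=1):
        if f > b:
            kept.append(k)
        else:
            break
    return kept


def correlate_with_axes(traits: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each trait with each PC axis, Holm-adjusted.

    One family per call: the Holm step-down adjustment spans every
    (trait, axis) pair. Zero-variance traits yield NaN r and p.
    """
    if len(traits) != len(scores):
        raise ValueError("traits and scores must have matching rows")
    if len(traits) < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    for t in traits.columns:
        x = traits[t].to_numpy(dtype=float)
        for a in scores.columns:
            y = scores[a].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"trait": t, "axis": a, "r": np.nan, "p": np.nan})
            else:
                r, p = stats.pearsonr(x, y)
                rows.append({"trait": t, "axis": a, "r": r, "p": p})
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = holm_adjust(out.loc[mask, "p"].to_numpy())
    out["p_holm"] = adj
    return out
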