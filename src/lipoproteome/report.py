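"""Diagnostics and figure-ready table emitters: PCA scores and volcano tables."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PcaScores", "pca_scores", "volcano_table"]


@dataclass
class PcaScores:
    """Sample scores on the first ``k`` principal components.

    ``scores`` is a samples x components frame (columns ``PC1`` ...);
    ``explained_variance_ratio`` holds the matching variance fractions,
    non-increasing and summing to at most 1.
    """

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_scores(log2_matrix: pd.DataFrame, k: int = 2) -> PcaScores:
    """PCA of samples from a complete (imputed) log2 intensity matrix.

    The matrix is proteins x samples; samples are the observations.
    Features (proteins) are mean-centered, not variance-scaled, and the
    decomposition is a plain SVD.  The sign of each component is fixed so
    its largest-magnitude protein loading is positive, making scores
    reproducible across runs.
    """
    if log2_matrix.isna().any().any():
        raise ValueError("pca_scores requires a complete (imputed) matrix")
    X = log2_matrix.to_numpy(dtype=float).T  # samples x proteins
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_k = min(n_samples, n_features)
    if k > max_k:
        raise ValueError(f"k = {k} exceeds min(n_samples, n_proteins) = {max_k}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(len(S)):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * S[:k]
    total = float(np.sum(S**2))
    evr = (S[:k] ** 2 / total) if total > 0 else np.zeros(k)
    frame = pd.DataFrame(scores, index=log2_matrix.columns, columns=[f"PC{j + 1}" for j in range(k)])
    return PcaScores(scores=frame, explained_variance_ratio=evr)


def volcano_table(
    results: pd.DataFrame,
    effect_col: str,
    p_col: str,
    threshold: float = 0.05,
    effect_is_ratio: bool = False,
) -> pd.DataFrame:
    """Figure-ready (effect, -log10 P, significance) table.

    With ``effect_is_ratio`` the effect column is a natural-scale ratio
    and an additional ``log2_effect`` column is emitted (ratio 1 maps to
    0).  Rows are ordered by ascending P then by index for determinism.
    """
    if effect_col not in results.columns or p_col not in results.columns:
        raise ValueError("results must carry the requested effect and P columns")
    out = pd.DataFrame(index=results.index)
    out["effect"] = results[effect_col].astype(float)
    if effect_is_ratio:
        out["log2_effect"] = np.log2(out["effect"])
    p = results[p_col].astype(float)
    with np.errstate(divide="ignore"):
        neg = np.where(p > 0, -np.log10(np.where(p > 0, p, 1.0)), math.inf)
    out["neg_log10_p"] = np.where(np.isnan(p), np.nan, neg)
    out["significant"] = p < threshold
    out["p"] = p
    return out.sort_values("p", kind="mergesort")  # stable: ties keep input order
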