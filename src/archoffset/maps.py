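"""Turnover surfaces: PCA-to-RGB maps and Procrustes comparison.

A transformed climate grid (cells x genomic-scaled predictors) is reduced
to its first three principal components and rescaled per channel to
0-255, so cells with similar predicted genomic composition share similar
colours.  Two such maps (e.g. all SNPs vs candidate SNPs) are compared by
superimposing one PC configuration on the other with the best
translation + rotation + uniform scaling; the per-cell residual distances
localize where the two models disagree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TurnoverMap:
    transformed: np.ndarray   # cells x predictors (genomic-scaled)
    pc_scores: np.ndarray     # cells x 3
    rgb: np.ndarray           # cells x 3, 0..255
    cell_ids: list

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cell_id": self.cell_ids,
            "R": self.rgb[:, 0], "G": self.rgb[:, 1], "B": self.rgb[:, 2],
        })
        for i in range(3):
            df[f"PC{i + 1}"] = self.pc_scores[:, i]
        return df


def pc_rgb(transformed_grid: np.ndarray, cell_ids=None) -> TurnoverMap:
    """First three PCs of a transformed grid, min-max rescaled to RGB.

    Degenerate dimensions (fewer than three non-constant PCs) are padded
    with zero channels; a fully constant grid maps to a single colour.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(transformed_grid, float)
    if X.ndim != 2:
        raise ValueError("transformed grid must be 2-D (cells x predictors)")
    ids = list(cell_ids) if cell_ids is not None else list(range(X.shape[0]))
    Xc = X - X.mean(0)
    rank = np.linalg.matrix_rank(Xc) if Xc.size else 0
    if rank == 0:
        warnings.warn("constant transformed grid: single-colour map")
        scores = np.zeros((X.shape[0], 3))
    else:
        k = min(3, rank, X.shape[1])
        scores = PCA(n_components=k, svd_solver="full").fit_transform(X)
        if k < 3:
            scores = np.column_stack(
                [scores, np.zeros((X.shape[0], 3 - k))]
            )
    rgb = np.zeros_like(scores)
    for ch in range(3):
        lo, hi = scores[:, ch].min(), scores[:, ch].max()
        if hi > lo:
            rgb[:, ch] = (scores[:, ch] - lo) / (hi - lo) * 255.0
    return TurnoverMap(transformed=X, pc_scores=scores, rgb=rgb, cell_ids=ids)


def procrustes_residuals(map_a: TurnoverMap, map_b: TurnoverMap) -> np.ndarray:
    """Per-cell residual after superimposing b's PCs on a's.

    Least-squares translation + rotation + uniform scaling of the 3-D PC
    configuration of ``map_b`` onto ``map_a``; identical-up-to-similarity
    configurations give all-zero residuals.
    """
    if map_a.cell_ids != map_b.cell_ids:
        raise ValueError("maps must share the same cell set (and order)")
    A = np.asarray(map_a.pc_scores, float)
    B = np.asarray(map_b.pc_scores, float)
    if A.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    if np.array_equal(A, B):
        if not A.any():
            raise ValueError("rank-deficient (constant) configuration")
        return np.zeros(A.shape[0])  # identity comparison is exactly zero
    Ac = A - A.mean(0)
    Bc = B - B.mean(0)
    nb = float((Bc ** 2).sum())
    if nb == 0 or float((Ac ** 2).sum()) == 0:
        raise ValueError("rank-deficient (constant) configuration")
    # optimal rotation R and scale s minimizing ||Ac - s * Bc R||
    M = Bc.T @ Ac
    U, S, Vt = np.linalg.svd(M)
    R = U @ Vt
    s = S.sum() / nb
    resid = Ac - s * (Bc @ R)
    return np.sqrt((resid ** 2).sum(1))
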