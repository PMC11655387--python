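"""Principal coordinates of neighbour matrices (PCNM).

Spatial eigenvectors from a truncated distance matrix, used as geography
proxies where an explicit lat/lon pair cannot enter a model (e.g. as
predictors for gradient forest).  Distances beyond the truncation are
replaced by four times the truncation before the principal-coordinates
decomposition, the standard Borcard–Legendre construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .popstruct import haversine_km

_POS_TOL = 1e-10


@dataclass
class PcnmAxes:
    vectors: np.ndarray       # site x axis, orthonormal eigenvectors
    eigenvalues: np.ndarray   # positive, non-increasing
    truncation_km: float
    n_positive: int

    @property
    def scores(self) -> np.ndarray:
        """Eigenvectors scaled by sqrt(eigenvalue) (PCoA coordinates)."""
        return self.vectors * np.sqrt(self.eigenvalues)

    def as_frame(self, site_ids=None):
        import pandas as pd
        cols = [f"PCNM{i + 1}" for i in range(self.vectors.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        if site_ids is not None:
            df.insert(0, "site_id", list(site_ids))
        return df


def pcnm(coords: np.ndarray, truncation_km: float,
         mode: str = "plane") -> PcnmAxes:
    """PCNM axes of site coordinates at a given truncation distance.

    Distances d_ij <= t are kept; larger ones are replaced by 4t.  The
    modified matrix is squared, Gower double-centered with -1/2, and
    eigendecomposed; axes with eigenvalue > 1e-10 * max eigenvalue are
    returned in decreasing order.  ``mode='plane'`` treats coords as x/y in
    km, ``'haversine'`` as lon/lat in degrees.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need >= 3 sites with 2-D coordinates")
    if truncation_km <= 0:
        raise ValueError("truncation must be positive")
    if mode == "plane":
        D = squareform(pdist(coords))
    elif mode == "haversine":
        lon, lat = coords[:, 0], coords[:, 1]
        D = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if D.max() == 0:
        raise ValueError("all coordinates identical: no spatial structure")

    t = float(truncation_km)
    Dt = np.where(D <= t, D, 4.0 * t)
    np.fill_diagonal(Dt, 0.0)
    n = Dt.shape[0]
    A = -0.5 * Dt ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > _POS_TOL * max(vals[0], _POS_TOL)
    if not pos.any():
        raise ValueError("no positive eigenvalues")
    return PcnmAxes(
        vectors=vecs[:, pos],
        eigenvalues=vals[pos],
        truncation_km=t,
        n_positive=int(pos.sum()),
    )


def retain_half_positive(axes: PcnmAxes, convention: str = "floor") -> PcnmAxes:
    """Keep the first half of the positive-eigenvalue axes.

    Axes with positive eigenvalues carry positive spatial correlation;
    their leading half (in eigenvalue order) captures broad-to-medium
    spatial scales.  ``convention`` is 'floor' (default) or 'ceil'.
    """
    n_pos = axes.n_positive
    if n_pos < 1:
        raise ValueError("no positive axes to retain")
    if convention == "floor":
        k = n_pos // 2
    elif convention == "ceil":
        k = (n_pos + 1) // 2
    else:
        raise ValueError(f"unknown convention {convention!r}")
    k = max(k, 1)
    return PcnmAxes(
        vectors=axes.vectors[:, :k],
        eigenvalues=axes.eigenvalues[:k],
        truncation_km=axes.truncation_km,
        n_positive=n_pos,
    )
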