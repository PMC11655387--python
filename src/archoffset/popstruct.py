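"""Genome-wide population-structure summaries.

Pairwise Weir–Cockerham F_ST (theta) with across-locus SD bands, genotype
PCA, identity-by-state distance, an isolation-by-distance sigmoid fit, and
threshold-based ancestry-group designation from an admixture Q matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genio import MISSING, GenotypeMatrix


@dataclass
class FstResult:
    """Multi-locus Weir–Cockerham theta for one group pair.

    ``theta`` is the ratio-of-averages estimate sum(a)/sum(a+b+c); the SD
    band is theta +/- the sample SD of per-locus theta, so the lower bound
    can be negative (which carries no biological meaning beyond zero).
    """

    pair: tuple[str, str]
    theta: float
    sd_band: tuple[float, float]
    n_loci_used: int
    n_loci_excluded: int


def _wc_components(counts0: np.ndarray, counts1: np.ndarray,
                   counts2: np.ndarray) -> tuple[np.ndarray, ...]:
    """Weir & Cockerham (1984) a, b, c variance components per locus.

    Inputs are per-population genotype counts (pops x loci) of dosage
    0, 1, 2.  Heterozygote frequencies are observed, not HWE-assumed.
    Loci where every population has < 2 genotypes or that are monomorphic
    overall come out with a = b = c = 0 and are flagged unusable.
    """
    n = (counts0 + counts1 + counts2).astype(float)        # diploids per pop
    r = n.shape[0]
    usable = (n >= 2).all(axis=0)
    n_safe = np.where(n > 0, n, np.nan)
    p = (2 * counts2 + counts1) / (2 * n_safe)             # alt freq per pop
    h = counts1 / n_safe                                   # observed het freq

    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n ** 2).sum(0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(0) / ((r - 1) * nbar)
        hbar = (n * h).sum(0) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0
            )
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0

    mono = np.isnan(pbar) | (pbar <= 0) | (pbar >= 1)
    usable &= ~mono
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def _group_genotype_counts(gm: GenotypeMatrix, members: np.ndarray):
    d = gm.dosage[members]
    return tuple(((d == g).sum(axis=0)) for g in (0, 1, 2))


def wc_fst(gm: GenotypeMatrix, groups: "pd.Series | np.ndarray | list",
           pairwise: bool = True) -> list[FstResult]:
    """Weir–Cockerham theta for every group pair (or all groups jointly).

    Loci monomorphic across the pair, or with fewer than two genotyped
    individuals in either group, are excluded from the sums and counted.
    """
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    results = []
    pairs = ([(i, j) for i in range(len(labels)) for j in range(len(labels))
              if i < j] if pairwise else [tuple(range(len(labels)))])
    for pair in pairs:
        sel_labels = [labels[k] for k in pair]
        counts = [np.stack(_group_genotype_counts(gm, groups == l))
                  for l in sel_labels]
        c0 = np.stack([c[0] for c in counts])
        c1 = np.stack([c[1] for c in counts])
        c2 = np.stack([c[2] for c in counts])
        a, b, c, usable = _wc_components(c0, c1, c2)
        denom = a + b + c
        total = denom[usable].sum()
        if total <= 0:
            raise ValueError(
                f"no usable polymorphic loci for pair {sel_labels}"
            )
        theta = a[usable].sum() / total
        with np.errstate(invalid="ignore", divide="ignore"):
            per_locus = a[usable] / denom[usable]
        per_locus = per_locus[np.isfinite(per_locus)]
        sd = float(per_locus.std(ddof=1)) if per_locus.size > 1 else 0.0
        results.append(FstResult(
            pair=tuple(sel_labels) if pairwise else ("all", "all"),
            theta=float(theta),
            sd_band=(float(theta - sd), float(theta + sd)),
            n_loci_used=int(usable.sum()),
            n_loci_excluded=int((~usable).sum()),
        ))
    return results


def fst_table(results: list[FstResult]) -> pd.DataFrame:
    """Square table of pairwise theta with the SD band in parentheses."""
    labels = sorted({l for r in results for l in r.pair})
    tab = pd.DataFrame("—", index=labels, columns=labels)
    for r in results:
        cell = f"{r.theta:.3f} ({r.sd_band[0]:.3f}, {r.sd_band[1]:.3f})"
        tab.loc[r.pair[0], r.pair[1]] = cell
        tab.loc[r.pair[1], r.pair[0]] = cell
    return tab


def pca_genotypes(gm: GenotypeMatrix, n_axes: int = 10):
    """PCA of the (complete) dosage matrix, centered per SNP.

    Returns (scores, explained_variance_ratio).  Axes are ordered by
    decreasing eigenvalue; requesting more axes than the rank truncates
    with a warning.
    """
    if gm.missing_mask().any():
        raise ValueError("pca_genotypes requires imputed (complete) data")
    from sklearn.decomposition import PCA

    X = gm.dosage.astype(float)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_axes > max_rank:
        warnings.warn(f"n_axes={n_axes} exceeds rank {max_rank}; truncating")
        n_axes = max_rank
    pca = PCA(n_components=n_axes, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def ibs_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Proportion of alleles not identical by state between individuals.

    d(i, j) = sum |g_i - g_j| / (2 * shared non-missing SNPs); a pair with
    no shared genotyped SNP gets NaN with a warning.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two individuals")
    d = gm.dosage.astype(float)
    d[d == MISSING] = np.nan
    n = gm.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[i] - d[i + 1:])        # NaN where either missing
        shared = np.sum(~np.isnan(diff), axis=1)
        mism = np.nansum(diff, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = mism / (2.0 * shared)
        out[i, i + 1:] = vals
        out[i + 1:, i] = vals
    if np.isnan(out).any():
        warnings.warn("some pairs share zero non-missing SNPs (NaN distance)")
    return out


def _sigmoid(x, L, k, x0, c):
    return L / (1.0 + np.exp(-k * (x - x0))) + c


@dataclass
class IbdFit:
    params: dict
    adjusted_r2: float
    p_value: float
    converged: bool

    def predict(self, x):
        x = np.asarray(x, float)
        if self.converged:
            return _sigmoid(x, self.params["L"], self.params["k"],
                            self.params["x0"], self.params["c"])
        return self._spline(x)


def fit_ibd(genetic_d: np.ndarray, geographic_km: np.ndarray,
            n_perm: int = 999, seed: int = 0) -> IbdFit:
    """Isolation-by-distance: sigmoid fit of genetic vs geographic distance.

    Fits g = L / (1 + exp(-k (x - x0))) + c by least squares on the pair
    lists (square matrices are flattened to their upper triangles) and
    reports the adjusted R^2 plus a Mantel-style permutation p value —
    pairwise distances are not independent, so an analytic p would be
    anticonservative.  Non-convergence falls back to a monotone spline,
    flagged via ``converged=False``.
    """
    g = np.asarray(genetic_d, float)
    x = np.asarray(geographic_km, float)
    square = g.ndim == 2
    if square:
        if g.shape != x.shape:
            raise ValueError("matrices must have matching shapes")
        iu = np.triu_indices(g.shape[0], k=1)
        gv, xv = g[iu], x[iu]
    else:
        gv, xv = g, x
        if gv.shape != xv.shape:
            raise ValueError("pair lists must have matching lengths")
    if (xv < 0).any():
        raise ValueError("geographic distances must be non-negative")

    def adj_r2(obs, pred, n_par):
        ss_res = np.sum((obs - pred) ** 2)
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        if ss_tot == 0:
            return 0.0
        r2 = 1 - ss_res / ss_tot
        n = len(obs)
        return 1 - (1 - r2) * (n - 1) / (n - n_par - 1)

    p0 = [gv.max() - gv.min() or 1.0, 0.05, np.median(xv), gv.min()]
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_sigmoid, xv, gv, p0=p0, maxfev=20000)
        pred = _sigmoid(xv, *popt)
        params = dict(zip(("L", "k", "x0", "c"), map(float, popt)))
    except RuntimeError:
        converged = False
        from scipy.interpolate import PchipInterpolator
        order = np.argsort(xv)
        xb = np.linspace(xv.min(), xv.max(), 10)
        yb = [gv[(xv >= lo) & (xv <= hi)].mean()
              for lo, hi in zip(xb[:-1], xb[1:])]
        yb = np.maximum.accumulate(np.nan_to_num(yb, nan=np.nanmin(gv)))
        spline = PchipInterpolator((xb[:-1] + xb[1:]) / 2, yb,
                                   extrapolate=True)
        pred = spline(xv)
        params = {}
    r2a = adj_r2(gv, pred, 4)

    # Mantel-style permutation of individuals (square input) or pairs
    rng = np.random.default_rng(seed)
    obs_corr = np.corrcoef(gv, pred)[0, 1] if np.std(pred) > 0 else 0.0
    count = 0
    for _ in range(n_perm):
        if square:
            perm = rng.permutation(g.shape[0])
            gp = g[np.ix_(perm, perm)][iu]
        else:
            gp = rng.permutation(gv)
        c_p = np.corrcoef(gp, pred)[0, 1] if np.std(pred) > 0 else 0.0
        if c_p >= obs_corr:
            count += 1
    p = (1 + count) / (1 + n_perm)
    fit = IbdFit(params=params, adjusted_r2=float(r2a), p_value=float(p),
                 converged=converged)
    if not converged:
        fit._spline = spline  # type: ignore[attr-defined]
    return fit


def assign_groups(q: np.ndarray, labels: list[str],
                  threshold: float = 0.9) -> list[str]:
    """Designate each individual by its majority ancestry, else 'hybrid'.

    An individual gets label ``labels[argmax]`` when that ancestry fraction
    is >= ``threshold`` (inclusive); otherwise it is a hybrid.  Rows must
    sum to 1 within 1e-3.
    """
    q = np.atleast_2d(np.asarray(q, float))
    if q.shape[1] != len(labels):
        raise ValueError("number of labels must equal number of columns (K)")
    sums = q.sum(axis=1)
    bad = np.where(np.abs(sums - 1) > 1e-3)[0]
    if bad.size:
        raise ValueError(f"Q row {bad[0]} sums to {sums[bad[0]]:.4f}, not 1")
    out = []
    for row in q:
        k = int(np.argmax(row))
        out.append(labels[k] if row[k] >= threshold else "hybrid")
    return out


def read_q_matrix(path: str) -> np.ndarray:
    """Read an ADMIXTURE-style whitespace-delimited Q matrix."""
    return np.loadtxt(path)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (degrees)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * 6371.0088 * np.arcsin(np.sqrt(h))


def geographic_distance_matrix(sample_meta: pd.DataFrame,
                               mode: str = "plane") -> np.ndarray:
    """Pairwise distances (km) from sample metadata.

    ``mode='plane'`` uses Euclidean distance on x/y km columns (synthetic
    fixtures); ``'haversine'`` uses lat/lon columns in degrees.
    """
    if mode == "plane":
        xy = sample_meta[["x", "y"]].to_numpy(float)
        from scipy.spatial.distance import squareform, pdist
        return squareform(pdist(xy))
    if mode == "haversine":
        lat = sample_meta["lat"].to_numpy(float)
        lon = sample_meta["lon"].to_numpy(float)
        return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    raise ValueError(f"unknown mode {mode!r}")
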