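"""Redundancy analysis: constrained ordination of a dosage matrix on
climate and geography, variance partitioning, permutation tests, outlier
(candidate SNP) detection and per-candidate predictor assignment.

RDA here is the classical construction: multivariate least squares of the
column-centered SNP matrix on standardized predictors, followed by an SVD
of the fitted values.  "Partial" models first residualize both sides on a
conditioning set.  Candidate loci are those loading more than ``sd_mult``
standard deviations from the mean on any of the first few constrained
axes, and each is assigned the predictor with which its dosage correlates
most strongly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

_COND_CAP = 1e8


@dataclass
class RdaModel:
    site_scores: np.ndarray       # n x k, U * S
    loadings: np.ndarray          # m x k, right singular vectors
    eigenvalues: np.ndarray       # k, S^2 / (n - 1)
    r2: float
    adjusted_r2: float
    n: int
    n_predictors: int
    n_conditions: int
    predictor_names: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)
    # retained for permutation testing
    _Y: np.ndarray | None = None
    _X: np.ndarray | None = None
    _Z: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0, keepdims=True)


def _standardize(M: np.ndarray) -> np.ndarray:
    M = _center(np.asarray(M, float))
    sd = M.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant predictor column; remove it first")
    return M / sd


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of M on [1, Z] (Z already centered)."""
    beta, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ beta


def _fit_core(Y: np.ndarray, X: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    k = int((s > 1e-10 * max(s[0], 1e-300)).sum()) if s.size else 0
    k = min(k, np.linalg.matrix_rank(X))
    return fitted, U[:, :k], s[:k], Vt[:k].T


def fit_rda(
    gm_or_Y, predictors: pd.DataFrame,
    condition: pd.DataFrame | None = None,
    check_collinearity: bool = True,
) -> RdaModel:
    """Constrained ordination of dosages on predictors.

    ``gm_or_Y`` is a complete :class:`GenotypeMatrix` or a raw response
    matrix.  Predictors are standardized internally; the response is
    column-centered.  With a conditioning set both sides are replaced by
    their least-squares residuals on it (partial RDA).  Collinear
    predictors (condition number above 1e8) are rejected.
    """
    if isinstance(gm_or_Y, GenotypeMatrix):
        if gm_or_Y.missing_mask().any():
            raise ValueError("fit_rda requires imputed (complete) dosages")
        Y = gm_or_Y.dosage.astype(float)
        snp_ids = [f"{c}:{p}" for c, p in
                   zip(gm_or_Y.snp_meta["chrom"], gm_or_Y.snp_meta["pos"])]
    else:
        Y = np.asarray(gm_or_Y, float)
        snp_ids = [f"col{j}" for j in range(Y.shape[1])]
    n = Y.shape[0]
    X = _standardize(predictors.to_numpy(float))
    p = X.shape[1]
    c = 0
    if check_collinearity and np.linalg.cond(X) > _COND_CAP:
        raise ValueError(
            "predictors are collinear (condition number too high); reduce "
            "them with genio.select_uncorrelated_predictors first"
        )
    if n <= p + 1:
        raise ValueError("need n individuals > n predictors + 1")
    Yc = _center(Y)
    Z = None
    if condition is not None:
        Z = _standardize(condition.to_numpy(float))
        c = Z.shape[1]
        if n <= p + c + 1:
            raise ValueError("need n > n predictors + n conditions + 1")
        Yc = _residualize(Yc, Z)
        X = _residualize(X, Z)

    fitted, U, s, V = _fit_core(Yc, X)
    ss_tot = float((Yc ** 2).sum())
    ss_fit = float((fitted ** 2).sum())
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    adj = 1 - (1 - r2) * (n - 1) / (n - p - c - 1)
    return RdaModel(
        site_scores=U * s,
        loadings=V,
        eigenvalues=s ** 2 / (n - 1),
        r2=r2,
        adjusted_r2=float(adj),
        n=n,
        n_predictors=p,
        n_conditions=c,
        predictor_names=list(predictors.columns),
        snp_ids=snp_ids,
        _Y=Yc, _X=X, _Z=Z,
    )


def _pseudo_f(Y: np.ndarray, X: np.ndarray, p: int, c: int) -> float:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    ss_fit = float((fitted ** 2).sum())
    ss_res = float(((Y - fitted) ** 2).sum())
    n = Y.shape[0]
    df_res = n - p - c - 1
    if ss_res <= 0 or df_res <= 0:
        return np.inf
    return (ss_fit / p) / (ss_res / df_res)


def permutation_test(model: RdaModel, n_perm: int = 99, seed: int = 0) -> float:
    """Permutation p value for the constrained fraction.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm); with 99 permutations the
    smallest attainable p is 0.01.  Plain models permute response rows;
    partial models permute residuals of the conditioning-only model
    (Freedman–Lane), keeping the conditioned structure fixed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y, X = model._Y, model._X
    if Y is None or X is None:
        raise ValueError("model was not fitted by fit_rda")
    rng = np.random.default_rng(seed)
    p, c = model.n_predictors, model.n_conditions
    f_obs = _pseudo_f(Y, X, p, c)
    # for partial models Y is already the reduced-model residual, so
    # permuting its rows is exactly the Freedman-Lane scheme
    count = 0
    for _ in range(n_perm):
        Yp = Y[rng.permutation(Y.shape[0])]
        if _pseudo_f(Yp, X, p, c) >= f_obs:
            count += 1
    return (1 + count) / (1 + n_perm)


@dataclass
class VariancePartition:
    """Adjusted-R^2 decomposition of full = climate_alone + geo_alone + joint."""

    full: float
    climate_alone: float
    geography_alone: float
    joint: float
    proportions: dict
    p_values: dict

    def as_table(self) -> pd.DataFrame:
        rows = [
            ("Full model (climate + geography)", self.full,
             self.proportions.get("full"), self.p_values.get("full")),
            ("Climate alone", self.climate_alone,
             self.proportions.get("climate_alone"),
             self.p_values.get("climate_alone")),
            ("Geography alone", self.geography_alone,
             self.proportions.get("geography_alone"),
             self.p_values.get("geography_alone")),
            ("Joint influence of climate and geography", self.joint,
             self.proportions.get("joint"), None),
        ]
        return pd.DataFrame(
            rows, columns=["model", "adjusted_R2",
                           "proportion_of_explainable", "p"]
        )


def variance_partition(
    gm_or_Y, climate_preds: pd.DataFrame, geo_preds: pd.DataFrame,
    n_perm: int = 99, seed: int = 0,
) -> VariancePartition:
    """Partition explainable genetic variance between climate and geography.

    full = adjR2(climate + geography); climate_alone = full - adjR2(geo);
    geography_alone = full - adjR2(climate); joint is the remainder, not
    testable by permutation.  The alone fractions are tested with partial
    models (Freedman–Lane permutations).
    """
    overlap = set(climate_preds.columns) & set(geo_preds.columns)
    if overlap:
        raise ValueError(f"predictor sets overlap: {sorted(overlap)}")
    both = pd.concat([climate_preds, geo_preds], axis=1)
    # the combined model may be rank-deficient under full confounding;
    # lstsq handles that, so skip the collinearity guard here
    m_full = fit_rda(gm_or_Y, both, check_collinearity=False)
    m_clim = fit_rda(gm_or_Y, climate_preds)
    m_geo = fit_rda(gm_or_Y, geo_preds)
    full = m_full.adjusted_r2
    climate_alone = full - m_geo.adjusted_r2
    geography_alone = full - m_clim.adjusted_r2
    joint = full - climate_alone - geography_alone

    if full > 0:
        proportions = {
            "full": 1.0,
            "climate_alone": climate_alone / full,
            "geography_alone": geography_alone / full,
            "joint": joint / full,
        }
    else:
        warnings.warn("full model explains nothing; proportions undefined")
        proportions = {k: np.nan for k in
                       ("full", "climate_alone", "geography_alone", "joint")}

    m_clim_part = fit_rda(gm_or_Y, climate_preds, condition=geo_preds)
    m_geo_part = fit_rda(gm_or_Y, geo_preds, condition=climate_preds)
    p_values = {
        "full": permutation_test(m_full, n_perm, seed),
        "climate_alone": permutation_test(m_clim_part, n_perm, seed + 1),
        "geography_alone": permutation_test(m_geo_part, n_perm, seed + 2),
    }
    return VariancePartition(
        full=full, climate_alone=climate_alone,
        geography_alone=geography_alone, joint=joint,
        proportions=proportions, p_values=p_values,
    )


@dataclass
class CandidateSet:
    """Outlier SNPs on the leading constrained axes."""

    table: pd.DataFrame   # snp_id, snp_index, axis, z, assigned_predictor, r
    n_axes: int
    sd_mult: float

    @property
    def snp_indices(self) -> np.ndarray:
        return self.table["snp_index"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def detect_outliers(model: RdaModel, n_axes: int = 3,
                    sd_mult: float = 4.0) -> CandidateSet:
    """Flag SNPs loading > sd_mult SD from the mean on any leading axis.

    The z-score uses each axis's own loading mean and SD.  A SNP flagged on
    several axes is reported once, with the axis of its largest |z|.
    """
    k = min(n_axes, model.n_axes)
    if k < 1:
        raise ValueError("model has no constrained axes")
    rows = {}
    for ax in range(k):
        lo = model.loadings[:, ax]
        sd = lo.std()
        if sd == 0:
            warnings.warn(f"axis {ax + 1} has zero loading SD; skipped")
            continue
        z = (lo - lo.mean()) / sd
        for j in np.where(np.abs(z) > sd_mult)[0]:
            if j not in rows or abs(z[j]) > abs(rows[j][2]):
                rows[j] = (model.snp_ids[j], ax + 1, float(z[j]))
    table = pd.DataFrame(
        [(sid, j, ax, zz) for j, (sid, ax, zz) in sorted(rows.items())],
        columns=["snp_id", "snp_index", "axis", "z"],
    )
    table["assigned_predictor"] = ""
    table["r"] = np.nan
    return CandidateSet(table=table, n_axes=k, sd_mult=sd_mult)


def assign_predictor(candidates: CandidateSet, gm_or_Y,
                     predictors: pd.DataFrame,
                     low_confidence_r: float = 0.1) -> CandidateSet:
    """Assign each candidate the predictor its dosage correlates with most.

    Ties go to the first predictor in declared order (flagged); |r| below
    ``low_confidence_r`` is flagged low-confidence; constant dosages stay
    unassigned with a warning.
    """
    Y = (gm_or_Y.dosage.astype(float)
         if isinstance(gm_or_Y, GenotypeMatrix) else np.asarray(gm_or_Y, float))
    X = predictors.to_numpy(float)
    Xc = _center(X)
    Xs = Xc / np.sqrt((Xc ** 2).sum(0))
    names = list(predictors.columns)
    tab = candidates.table
    assigned, rvals, flags = [], [], []
    for j in tab["snp_index"]:
        y = Y[:, j]
        yc = y - y.mean()
        ssy = float((yc ** 2).sum())
        if ssy == 0:
            warnings.warn(f"candidate {j} has constant dosage; unassigned")
            assigned.append("")
            rvals.append(np.nan)
            flags.append("constant")
            continue
        r = (Xs.T @ yc) / np.sqrt(ssy)
        best = int(np.argmax(np.abs(r)))
        tie = np.isclose(np.abs(r), np.abs(r[best])).sum() > 1
        flag = []
        if tie:
            flag.append("tie")
        if abs(r[best]) < low_confidence_r:
            flag.append("low_confidence")
        assigned.append(names[best])
        rvals.append(float(r[best]))
        flags.append(",".join(flag))
    tab = tab.assign(assigned_predictor=assigned, r=rvals, flag=flags)
    return CandidateSet(table=tab, n_axes=candidates.n_axes,
                        sd_mult=candidates.sd_mult)
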