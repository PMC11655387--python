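"""Gradient-forest turnover functions.

For every SNP a small regression forest is fitted on the climate + spatial
predictor table.  Split impurity reductions are pooled, per predictor,
into equal-frequency bins of the predictor's observed range, weighted by
each SNP's out-of-bag R^2, and cumulated into a non-decreasing step
function f_v ("cumulative importance").  f_v(min) = 0 and f_v(max) equals
the predictor's overall R^2-weighted importance, so mapping a climate
table through the f_v's re-expresses it in "genomic-scaled" units:
distances in the transformed space approximate expected allelic turnover.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

log = logging.getLogger(__name__)


def max_level_rule(n_samples: int, rounding: str = "nearest") -> int:
    """Tree-depth cap: log2(0.368 * n / 2), at least 1.

    0.368 (= 1/e) is the expected out-of-bag fraction of a bootstrap
    sample; the rule caps depth so terminal nodes keep a handful of
    in-bag observations.  Rounding is to the nearest integer by default
    ('floor' available).
    """
    if n_samples < 12:
        raise ValueError("need at least 12 samples for a sensible depth cap")
    raw = np.log2(0.368 * n_samples / 2.0)
    lvl = int(np.floor(raw)) if rounding == "floor" else int(round(raw))
    return max(1, lvl)


@dataclass(frozen=True)
class GfParams:
    """Forest and binning settings.

    ntree trees per SNP; corr_threshold is the predictor-correlation level
    above which a warning is logged (impurity importances of correlated
    predictors share credit); max_level caps tree depth (None applies
    :func:`max_level_rule`); nbins equal-frequency bins per predictor;
    only SNPs with out-of-bag R^2 above min_r2 contribute.
    """

    ntree: int = 500
    corr_threshold: float = 0.5
    max_level: int | None = None
    nbins: int = 50
    min_r2: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.max_level is not None and self.max_level < 1:
            raise ValueError("max_level must be >= 1")
        if self.nbins < 10:
            raise ValueError("nbins must be >= 10")


@dataclass
class TurnoverModel:
    """Per-predictor cumulative-importance step functions.

    For predictor v, ``bin_edges[v]`` has B+1 sorted edges spanning the
    training range and ``cum_importance[v]`` has B non-decreasing values;
    f_v(x) is the cumulative importance of all bins whose right edge is
    <= x (0 below the first right edge, the overall importance at and
    beyond the training maximum).
    """

    predictor_names: list[str]
    bin_edges: dict
    cum_importance: dict
    overall_importance: dict
    snp_r2: np.ndarray
    params: GfParams
    model_id: str = "gf"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for v in self.predictor_names:
            ci = np.asarray(self.cum_importance[v])
            if ci.size and np.any(np.diff(ci) < -1e-12):
                raise ValueError(f"cumulative importance for {v} decreases")

    def f(self, name: str, x) -> np.ndarray:
        """Evaluate the turnover step function of one predictor."""
        if name not in self.cum_importance:
            raise KeyError(f"predictor {name!r} not in model")
        edges = np.asarray(self.bin_edges[name])
        cum = np.asarray(self.cum_importance[name])
        x = np.clip(np.asarray(x, float), edges[0], edges[-1])
        # count bins whose right edge is <= x
        idx = np.searchsorted(edges[1:], x, side="right")
        out = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
        return out

    def total_importance(self) -> float:
        return float(sum(self.overall_importance.values()))

    def to_json(self, path: str) -> None:
        payload = {
            "model_id": self.model_id,
            "predictor_names": self.predictor_names,
            "bin_edges": {k: list(map(float, v))
                          for k, v in self.bin_edges.items()},
            "cum_importance": {k: list(map(float, v))
                               for k, v in self.cum_importance.items()},
            "overall_importance": {k: float(v) for k, v in
                                   self.overall_importance.items()},
            "snp_r2": [float(v) for v in self.snp_r2],
            "params": self.params.__dict__,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "TurnoverModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            predictor_names=d["predictor_names"],
            bin_edges={k: np.asarray(v) for k, v in d["bin_edges"].items()},
            cum_importance={k: np.asarray(v)
                            for k, v in d["cum_importance"].items()},
            overall_importance=d["overall_importance"],
            snp_r2=np.asarray(d["snp_r2"]),
            params=GfParams(**d["params"]),
            model_id=d["model_id"],
            meta=d.get("meta", {}),
        )


def _equal_frequency_edges(x: np.ndarray, nbins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, nbins + 1))
    edges = np.unique(qs)
    if edges.size < 2:
        edges = np.array([edges[0], edges[0] + 1e-9])
    return edges


def _tree_split_importance(tree):
    """Arrays (features, thresholds, impurity decreases) over internal nodes."""
    t = tree.tree_
    feat = t.feature
    internal = feat >= 0
    w = t.weighted_n_node_samples
    imp = t.impurity
    wi = w * imp
    d = (wi - wi[t.children_left] - wi[t.children_right])[internal] / w[0]
    keep = d > 0
    return feat[internal][keep], t.threshold[internal][keep], d[keep]


def fit_gf(
    gm_or_Y, predictors: pd.DataFrame, params: GfParams | None = None,
    model_id: str = "gf",
) -> TurnoverModel:
    """Fit per-SNP regression forests and pool split importances.

    Per SNP: a seeded random forest (bootstrap, depth-capped) gives an
    out-of-bag R^2 and per-split impurity reductions.  Each split's
    reduction is accrued to the bin of its predictor's observed range
    containing the split threshold.  A SNP's binned mass is rescaled so it
    sums to R^2 * (that predictor's share of the SNP's split importance),
    i.e. to R^2 overall; pooling over positive-R^2 SNPs and cumulating
    per predictor yields the turnover functions.
    """
    from sklearn.ensemble import RandomForestRegressor

    params = params or GfParams()
    if isinstance(gm_or_Y, GenotypeMatrix):
        if gm_or_Y.missing_mask().any():
            raise ValueError("fit_gf requires imputed (complete) dosages")
        Y = gm_or_Y.dosage.astype(float)
    else:
        Y = np.asarray(gm_or_Y, float)
    X = predictors.to_numpy(float)
    names = list(predictors.columns)
    n, n_pred = X.shape
    if Y.shape[0] != n:
        raise ValueError("dosage and predictor tables disagree on samples")

    const = [v for v, s in zip(names, X.std(0)) if s == 0]
    if const:
        warnings.warn(f"constant predictors get zero importance: {const}")
    corr = pd.DataFrame(X, columns=names).corr().abs()
    hot = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]
           if corr.loc[a, b] > params.corr_threshold]
    if hot:
        log.warning(
            "predictor pairs correlated above %.2f: %s — impurity "
            "importances will share credit between them",
            params.corr_threshold, hot,
        )

    depth = params.max_level or max_level_rule(n)
    edges = {v: _equal_frequency_edges(X[:, j], params.nbins)
             for j, v in enumerate(names)}
    binned = {v: np.zeros(len(edges[v]) - 1) for v in names}

    seed_seq = np.random.SeedSequence(params.seed)
    snp_seeds = seed_seq.generate_state(Y.shape[1]) % (2 ** 31 - 1)
    r2s = np.full(Y.shape[1], np.nan)
    n_used = 0
    for s in range(Y.shape[1]):
        y = Y[:, s]
        if y.std() == 0:
            r2s[s] = -np.inf
            continue
        rf = RandomForestRegressor(
            n_estimators=params.ntree,
            max_depth=depth,
            max_features=max(1, n_pred // 3),
            bootstrap=True,
            oob_score=True,
            random_state=int(snp_seeds[s]),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
            rf.fit(X, y)
        r2 = rf.oob_score_
        r2s[s] = r2
        if not np.isfinite(r2) or r2 <= params.min_r2:
            continue
        parts = [_tree_split_importance(tree) for tree in rf.estimators_]
        feats = np.concatenate([p[0] for p in parts])
        thrs = np.concatenate([p[1] for p in parts])
        dimps = np.concatenate([p[2] for p in parts])
        total = float(dimps.sum())
        if total <= 0:
            continue
        raw = {}
        for fj, v in enumerate(names):
            sel = feats == fj
            e = edges[v]
            if sel.any():
                k = np.clip(np.searchsorted(e, thrs[sel], side="right") - 1,
                            0, len(e) - 2)
                raw[v] = np.bincount(k, weights=dimps[sel],
                                     minlength=len(e) - 1)
            else:
                raw[v] = np.zeros(len(e) - 1)
        scale = r2 / total
        for v in names:
            binned[v] += raw[v] * scale
        n_used += 1

    if n_used == 0:
        raise ValueError("no predictive loci: every out-of-bag R^2 <= min_r2")

    cum = {v: np.cumsum(binned[v]) for v in names}
    overall = {v: float(cum[v][-1]) if cum[v].size else 0.0 for v in names}
    return TurnoverModel(
        predictor_names=names,
        bin_edges=edges,
        cum_importance=cum,
        overall_importance=overall,
        snp_r2=r2s,
        params=params,
        model_id=model_id,
        meta={"n_samples": n, "n_snps": int(Y.shape[1]),
              "n_snps_used": n_used, "max_level": depth},
    )


def transform(model: TurnoverModel, climate_rows: pd.DataFrame,
              use_predictors: list[str] | None = None) -> np.ndarray:
    """Map climate rows into genomic-scaled space.

    Output[i, v] = f_v(climate_rows[i, v]); values outside the training
    range are clamped (step functions are flat beyond their endpoints).
    """
    preds = use_predictors or model.predictor_names
    for v in preds:
        if v not in model.predictor_names:
            raise KeyError(f"predictor {v!r} absent from model")
        if v not in climate_rows.columns:
            raise KeyError(f"predictor {v!r} absent from climate table")
    out = np.column_stack([
        model.f(v, climate_rows[v].to_numpy(float)) for v in preds
    ])
    return out
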