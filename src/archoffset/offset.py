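"""Genomic offset, conservation scenarios and the climate suitability index.

The genomic offset between a seed source (historic climate) and a planting
site (future climate) is the Euclidean distance between the two climates
after both are mapped through a turnover model's cumulative-importance
functions — a proxy for the expected mismatch between the source's
(assumed locally adapted) allele frequencies and those favoured at the
site.  Three management scenarios are compared: keep each population in
place (status quo), give each existing site its best-matched non-local
source (ecosystem preservation), and move each population to its
best-matched site (species preservation).  The suitability index rescales
offsets to [0, 1] by the largest offset in the pairing table: 1 means the
site's future climate is genomically identical to the source's climate of
origin, 0 marks the worst pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import CLIMATE_PREDICTORS
from .gfturnover import TurnoverModel, transform


@dataclass
class OffsetTable:
    """Seed-source x planting-site offsets for one turnover model."""

    offsets: pd.DataFrame      # index = sources, columns = sites
    model_id: str
    scenario: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.offsets.to_numpy() < 0).any():
            raise ValueError("offsets must be non-negative")

    @property
    def max_offset(self) -> float:
        return float(self.offsets.to_numpy().max())

    def require_same_model(self, other: "OffsetTable") -> None:
        if self.model_id != other.model_id:
            raise ValueError(
                f"offsets from different models ({self.model_id!r} vs "
                f"{other.model_id!r}) are not comparable"
            )


def genomic_offset(model: TurnoverModel, source_hist_row: pd.DataFrame,
                   site_future_row: pd.DataFrame,
                   use_predictors: list[str] | None = None) -> float:
    """Offset for one source/site pair (Euclidean norm in turnover space)."""
    preds = use_predictors or _default_predictors(model)
    a = transform(model, source_hist_row, preds)
    b = transform(model, site_future_row, preds)
    return float(np.linalg.norm(a - b))


def _default_predictors(model: TurnoverModel) -> list[str]:
    """Climate predictors only: spatial (PCNM) axes are excluded because
    unsampled grid cells have no training-time PCNM coordinates."""
    preds = [v for v in model.predictor_names if not v.startswith("PCNM")]
    if not preds:
        raise ValueError("model has no non-spatial predictors")
    return preds


def offset_table(
    model: TurnoverModel,
    sources_hist: pd.DataFrame,
    sites_future: pd.DataFrame,
    source_ids=None,
    site_ids=None,
    use_predictors: list[str] | None = None,
    include_spatial: bool = False,
) -> OffsetTable:
    """All-pairs offsets between source historic and site future climates."""
    preds = use_predictors or (
        list(model.predictor_names) if include_spatial
        else _default_predictors(model)
    )
    A = transform(model, sources_hist, preds)
    B = transform(model, sites_future, preds)
    diff = A[:, None, :] - B[None, :, :]
    O = np.sqrt((diff ** 2).sum(-1))
    idx = list(source_ids) if source_ids is not None else list(range(len(A)))
    cols = list(site_ids) if site_ids is not None else list(range(len(B)))
    return OffsetTable(
        offsets=pd.DataFrame(O, index=idx, columns=cols),
        model_id=model.model_id,
        meta={"predictors": preds},
    )


def scenario_status_quo(model: TurnoverModel, populations: pd.DataFrame,
                        use_predictors: list[str] | None = None) -> pd.Series:
    """Offset of each population against its own cell's future climate.

    ``populations`` needs one row per population with historic and future
    predictor values in columns ``<pred>`` and ``<pred>_future``.
    """
    preds = use_predictors or _default_predictors(model)
    fut_cols = [f"{v}_future" for v in preds]
    missing = [c for c in fut_cols if c not in populations.columns]
    if missing:
        raise ValueError(f"missing future climate columns: {missing}")
    hist = populations[preds]
    fut = populations[fut_cols].rename(
        columns=dict(zip(fut_cols, preds))
    )
    A = transform(model, hist, preds)
    B = transform(model, fut, preds)
    vals = np.sqrt(((A - B) ** 2).sum(1))
    idx = (populations["cell_id"] if "cell_id" in populations.columns
           else populations.index)
    return pd.Series(vals, index=idx, name="status_quo_offset")


def scenario_ecosystem(offsets: OffsetTable) -> pd.DataFrame:
    """Per site: the minimum offset over sources and the best source(s)."""
    O = offsets.offsets
    if O.shape[0] == 0:
        raise ValueError("empty source set")
    best = O.idxmin(axis=0)
    mins = O.min(axis=0)
    all_best = [
        ",".join(str(s) for s in O.index[np.isclose(O[c], mins[c])])
        for c in O.columns
    ]
    return pd.DataFrame({
        "site": O.columns,
        "min_offset": mins.to_numpy(),
        "best_source": best.to_numpy(),
        "tied_sources": all_best,
    }).set_index("site")


def scenario_species(offsets: OffsetTable, site_pool: str = "sampled") -> pd.DataFrame:
    """Per population: the minimum offset over candidate sites and its argmin.

    ``site_pool`` is a label recorded in the output ('sampled' or
    'all_cells'); the candidate sites are the columns of ``offsets``.
    """
    O = offsets.offsets
    if O.shape[1] == 0:
        raise ValueError("empty site pool")
    best = O.idxmin(axis=1)
    mins = O.min(axis=1)
    return pd.DataFrame({
        "population": O.index,
        "min_offset": mins.to_numpy(),
        "best_site": best.to_numpy(),
        "site_pool": site_pool,
    }).set_index("population")


def suitability(offsets: OffsetTable) -> pd.DataFrame:
    """Climate suitability S = 1 - O / max(O) over the full pairing table.

    S = 1 exactly where the offset is zero (site future climate identical,
    in genomic-scaled space, to the source's climate of origin); S = 0 at
    the maximal-offset pair.  All-zero offset tables are a degenerate
    S = 1 everywhere, warned about.
    """
    O = offsets.offsets.to_numpy(float)
    m = O.max()
    if m <= 0:
        warnings.warn("all offsets are zero; suitability is 1 everywhere")
        S = np.ones_like(O)
    else:
        S = 1.0 - O / m
    return pd.DataFrame(S, index=offsets.offsets.index,
                        columns=offsets.offsets.columns)


@dataclass
class ScenarioReport:
    """Bundle of the three scenarios plus the suitability matrix."""

    status_quo: pd.Series
    ecosystem: pd.DataFrame
    species_sampled: pd.DataFrame
    species_all: pd.DataFrame | None
    suitability: pd.DataFrame
    model_id: str

    def check_dominance(self) -> None:
        """Assert the scenario-dominance invariants (raise on violation)."""
        sq = self.status_quo
        eco = self.ecosystem["min_offset"]
        common = sq.index.intersection(eco.index)
        if not (eco.loc[common] <= sq.loc[common] + 1e-12).all():
            raise AssertionError("ecosystem min exceeds status quo somewhere")
        sp = self.species_sampled["min_offset"]
        common = sq.index.intersection(sp.index)
        if not (sp.loc[common] <= sq.loc[common] + 1e-12).all():
            raise AssertionError("species min exceeds status quo somewhere")
        if self.species_all is not None:
            spa = self.species_all["min_offset"]
            common = sp.index.intersection(spa.index)
            if not (spa.loc[common] <= sp.loc[common] + 1e-12).all():
                raise AssertionError("all-cells species min exceeds sampled")


def run_scenarios(
    model: TurnoverModel,
    populations: pd.DataFrame,
    all_sites_future: pd.DataFrame | None = None,
    all_site_ids=None,
    use_predictors: list[str] | None = None,
) -> ScenarioReport:
    """Compute the three conservation scenarios on sampled populations.

    ``populations``: one row per sampled population (cell) with historic
    predictors and ``<pred>_future`` columns.  ``all_sites_future``
    optionally widens the species-preservation site pool to every grid
    cell (its rows are future-slice predictor values).
    """
    preds = use_predictors or _default_predictors(model)
    ids = (populations["cell_id"].tolist()
           if "cell_id" in populations.columns else list(populations.index))
    fut_cols = [f"{v}_future" for v in preds]
    hist = populations[preds]
    fut = populations[fut_cols].rename(columns=dict(zip(fut_cols, preds)))

    table = offset_table(model, hist, fut, source_ids=ids, site_ids=ids,
                         use_predictors=preds)
    sq = pd.Series(np.diag(table.offsets.to_numpy()), index=ids,
                   name="status_quo_offset")
    eco = scenario_ecosystem(table)
    sp_sampled = scenario_species(table, site_pool="sampled")
    sp_all = None
    if all_sites_future is not None:
        table_all = offset_table(
            model, hist, all_sites_future, source_ids=ids,
            site_ids=all_site_ids, use_predictors=preds,
        )
        sp_all = scenario_species(table_all, site_pool="all_cells")
    return ScenarioReport(
        status_quo=sq,
        ecosystem=eco,
        species_sampled=sp_sampled,
        species_all=sp_all,
        suitability=suitability(table),
        model_id=model.model_id,
    )


def best_pairs(suit: pd.DataFrame, top_k: int = 1) -> pd.DataFrame:
    """Rank sources per site by descending suitability.

    Rows (sites) are ordered by mean suitability, best first, matching the
    usual seed-sourcing heat-map layout; per site the top ``top_k``
    sources are listed with their rank.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    site_order = suit.mean(axis=0).sort_values(ascending=False).index
    rows = []
    for site in site_order:
        ranked = suit[site].sort_values(ascending=False, kind="mergesort")
        for rank, (src, s) in enumerate(ranked.head(top_k).items(), 1):
            rows.append((site, rank, src, float(s)))
    return pd.DataFrame(rows, columns=["site", "rank", "source", "suitability"])
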