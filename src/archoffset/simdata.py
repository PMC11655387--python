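"""Synthetic island archipelagos with climate grids and structured genotypes.

The generator emulates the study system this pipeline targets: a handful of
islands on a km plane, each a cluster of climate-grid cells carrying six
predictors (BIO5, BIO6, BIO15, BIO18, BIO19, elevation) for a historic and a
displaced future slice; island-structured genotypes drawn under the
Balding–Nichols model; a minority of loci whose allele frequencies follow a
climate cline; an optional two-pool introgression gradient; and per-genotype
missingness, optionally depth-driven.  Every downstream stage (filtering,
F_ST, RDA, PCNM, gradient forest, offsets) is testable against the emitted
truth table without any external download.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import CLIMATE_PREDICTORS, MISSING, GenotypeMatrix, write_vcf


@dataclass(frozen=True)
class GradientSpec:
    """Linear spatial field for one predictor: base + slope_x*x + slope_y*y + noise.

    Units are the predictor's own (degC, mm, CV%, m); slopes are per km.
    """

    base: float
    slope_x: float = 0.0
    slope_y: float = 0.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class ShiftSpec:
    """Deterministic future displacement for one predictor.

    ``delta`` is a uniform offset; ``slope_y`` lets the displacement vary
    north-south (per km), mimicking latitude-dependent warming.
    """

    delta: float
    slope_y: float = 0.0


#: default historic fields: cooler/wetter north (large y), warmer/drier south,
#: magnitudes in the range of Mediterranean-climate coastal islands
DEFAULT_GRADIENTS: dict[str, GradientSpec] = {
    # noise levels keep pairwise predictor correlations at or below ~0.7,
    # emulating a predictor set already reduced by collinearity screening
    "BIO5": GradientSpec(base=27.0, slope_y=-0.02, noise_sd=0.9),    # degC
    "BIO6": GradientSpec(base=7.0, slope_y=-0.01, slope_x=0.004,
                         noise_sd=0.6),                              # degC
    "BIO15": GradientSpec(base=75.0, slope_x=0.05, noise_sd=4.0),    # CV %
    "BIO18": GradientSpec(base=12.0, slope_y=0.04, slope_x=-0.02,
                          noise_sd=3.0),                             # mm
    "BIO19": GradientSpec(base=230.0, slope_y=0.3, slope_x=-0.15,
                          noise_sd=35.0),                            # mm
    "elev": GradientSpec(base=250.0, noise_sd=80.0),                 # m
}

#: default mid-century displacement: ~2.5 degC summer warming, drier winters
DEFAULT_FUTURE_SHIFT: dict[str, ShiftSpec] = {
    "BIO5": ShiftSpec(delta=2.5),
    "BIO6": ShiftSpec(delta=2.0),
    "BIO15": ShiftSpec(delta=5.0),
    "BIO18": ShiftSpec(delta=-4.0),
    "BIO19": ShiftSpec(delta=-40.0),
    "elev": ShiftSpec(delta=0.0),
}


@dataclass
class Archipelago:
    """Islands as clusters of climate cells on a km plane, two time slices.

    ``grid`` has one row per cell with columns cell_id, island, x, y and the
    six predictors; ``future`` shares the identical cell set.  The per-cell
    ``displacement`` is future minus historic, exactly as specified by the
    shift spec that built it.
    """

    grid: pd.DataFrame
    future: pd.DataFrame
    islands: list[str]
    seed: int

    def __post_init__(self) -> None:
        if not (self.grid["cell_id"] == self.future["cell_id"]).all():
            raise ValueError("historic and future layers must share cells")
        for v in CLIMATE_PREDICTORS:
            if v not in self.grid.columns or v not in self.future.columns:
                raise ValueError(f"predictor {v} missing from a slice")

    @property
    def displacement(self) -> pd.DataFrame:
        d = self.future[CLIMATE_PREDICTORS].to_numpy() - \
            self.grid[CLIMATE_PREDICTORS].to_numpy()
        out = self.grid[["cell_id", "island", "x", "y"]].copy()
        out[CLIMATE_PREDICTORS] = d
        return out

    def cells_of(self, island: str) -> pd.DataFrame:
        return self.grid[self.grid["island"] == island]

    def scaled_displacement(self, alpha: float) -> "Archipelago":
        """Archipelago with the future slice at a scaled displacement."""
        fut = self.grid.copy()
        fut[CLIMATE_PREDICTORS] = (
            self.grid[CLIMATE_PREDICTORS].to_numpy()
            + alpha * (self.future[CLIMATE_PREDICTORS].to_numpy()
                       - self.grid[CLIMATE_PREDICTORS].to_numpy())
        )
        return Archipelago(self.grid, fut, self.islands, self.seed)


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    loci: pd.DataFrame      # locus, label (neutral|adaptive), driver, effect_b
    fst: float
    admixture: np.ndarray   # per-individual fraction of pool-A ancestry

    def __post_init__(self) -> None:
        labels = set(self.loci["label"])
        if not labels <= {"neutral", "adaptive"}:
            raise ValueError(f"unknown locus labels: {labels}")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        q = np.asarray(self.admixture, float)
        if ((q < 0) | (q > 1)).any():
            raise ValueError("admixture proportions must lie in [0, 1]")


def make_archipelago(
    n_islands: int = 6,
    cells_per_island: int = 10,
    climate_gradients: dict[str, GradientSpec] | None = None,
    future_shift: dict[str, ShiftSpec] | None = None,
    seed: int = 0,
    island_spacing_km: float = 60.0,
    island_radius_km: float = 8.0,
    shift_scale_by_island: dict[str, float] | None = None,
) -> Archipelago:
    """Lay out ``n_islands`` cell clusters and evaluate both climate slices.

    Islands sit on a loose north-west to south-east diagonal (alternating
    offsets) so the default gradients produce a cool/wet north versus
    warm/dry south contrast.  ``shift_scale_by_island`` optionally rescales
    the future displacement per island (e.g. 0.0 pins an island's future
    climate to its historic one).
    """
    if n_islands < 1:
        raise ValueError(f"n_islands must be >= 1, got {n_islands}")
    if cells_per_island < 1:
        raise ValueError(f"cells_per_island must be >= 1, got {cells_per_island}")
    gradients = dict(DEFAULT_GRADIENTS, **(climate_gradients or {}))
    shifts = dict(DEFAULT_FUTURE_SHIFT, **(future_shift or {}))
    rng = np.random.default_rng(seed)

    labels = [f"island_{chr(ord('A') + i)}" for i in range(n_islands)]
    # northern row (first half) at high y, southern row at low y, with the
    # east-west position staggered so x and y are not collinear across cells
    n_north = (n_islands + 1) // 2
    rows = []
    for i, label in enumerate(labels):
        if i < n_north:
            cx = i * island_spacing_km
            cy = 2.2 * island_spacing_km + (island_spacing_km / 4 if i % 2 else 0)
        else:
            j = i - n_north
            cx = (j + 0.5) * island_spacing_km
            cy = (island_spacing_km / 4 if j % 2 else 0.0)
        for c in range(cells_per_island):
            ang = rng.uniform(0, 2 * np.pi)
            rad = island_radius_km * np.sqrt(rng.uniform())
            rows.append((f"{label}_c{c}", label,
                         cx + rad * np.cos(ang), cy + rad * np.sin(ang)))
    grid = pd.DataFrame(rows, columns=["cell_id", "island", "x", "y"])

    for v in CLIMATE_PREDICTORS:
        g = gradients[v]
        noise = rng.normal(0.0, g.noise_sd, len(grid)) if g.noise_sd > 0 else 0.0
        grid[v] = g.base + g.slope_x * grid["x"] + g.slope_y * grid["y"] + noise

    scale = np.ones(len(grid))
    if shift_scale_by_island:
        scale = grid["island"].map(
            lambda s: shift_scale_by_island.get(s, 1.0)
        ).to_numpy(float)
    future = grid.copy()
    for v in CLIMATE_PREDICTORS:
        s = shifts[v]
        future[v] = grid[v] + scale * (s.delta + s.slope_y * grid["y"])
    return Archipelago(grid, future, labels, seed)


def _balding_nichols(rng, p0: np.ndarray, fst: float, size: tuple) -> np.ndarray:
    """Island allele frequencies around ancestral p0 at differentiation fst."""
    if fst <= 0:
        return np.broadcast_to(p0, size).copy()
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    return rng.beta(a, b, size=size)


def simulate_genotypes(
    arch: Archipelago,
    n_per_island: int = 20,
    n_neutral: int = 1800,
    n_adaptive: int = 200,
    fst: float = 0.05,
    effect_b: float = 2.0,
    admixture_spec: dict[str, float] | None = None,
    adaptive_driver: str | None = None,
    missing_rate: float = 0.0,
    depth_missingness: bool = False,
    mean_depth: float = 20.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw island-structured genotypes with planted climate-adaptive loci.

    Neutral loci: ancestral frequency p0 ~ U(0.05, 0.95), island frequencies
    Beta(p0(1-F)/F, (1-p0)(1-F)/F) (Balding–Nichols at F = ``fst``).
    Adaptive loci: per-cell frequency logistic(logit(p0) + b*z) with z the
    standardized driving predictor (cycled over the six), so allele
    frequencies follow the climate cline with sign(b).  Genotypes are
    Binomial(2, p).  ``admixture_spec`` maps island -> expected fraction of a
    second ancestral pool, emulating an introgression gradient.  Missingness
    is per-genotype Bernoulli at ``missing_rate``, or depth-driven when
    ``depth_missingness`` (DP ~ Poisson(mean_depth), masked below 5).
    """
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0, 1)")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if n_adaptive > 0 and effect_b == 0:
        warnings.warn("effect_b = 0: adaptive loci are indistinguishable "
                      "from neutral loci")
    rng = np.random.default_rng(seed)
    n_loci = n_neutral + n_adaptive

    # sample individuals into cells
    samples = []
    for label in arch.islands:
        cells = arch.cells_of(label)
        pick = rng.integers(0, len(cells), n_per_island)
        for k, ci in enumerate(pick):
            cell = cells.iloc[ci]
            samples.append((f"{label}_s{k}", label, cell["cell_id"],
                            cell["x"], cell["y"]))
    sample_meta = pd.DataFrame(
        samples, columns=["id", "island", "cell_id", "x", "y"]
    )
    n_ind = len(sample_meta)
    island_idx = sample_meta["island"].map(
        {l: i for i, l in enumerate(arch.islands)}
    ).to_numpy()

    # climate at each individual's cell, standardized over cells
    grid = arch.grid.set_index("cell_id")
    clim = grid.loc[sample_meta["cell_id"], CLIMATE_PREDICTORS].to_numpy(float)
    mu = arch.grid[CLIMATE_PREDICTORS].mean().to_numpy()
    sd = arch.grid[CLIMATE_PREDICTORS].std().to_numpy()
    sd[sd == 0] = 1.0
    z = (clim - mu) / sd

    p0 = rng.uniform(0.05, 0.95, n_loci)
    # pool A: island-structured Balding-Nichols frequencies
    pA = _balding_nichols(rng, p0, fst, (len(arch.islands), n_loci))
    # pool B: an independent draw around its own ancestral frequencies,
    # standing in for the second (introgressing) species
    p0B = rng.uniform(0.05, 0.95, n_loci)
    pB = _balding_nichols(rng, p0B, max(fst, 0.02), (1, n_loci))[0]

    if adaptive_driver is not None:
        if adaptive_driver not in CLIMATE_PREDICTORS:
            raise ValueError(f"unknown predictor {adaptive_driver!r}")
        drivers = [adaptive_driver] * n_adaptive
    else:
        drivers = [CLIMATE_PREDICTORS[i % len(CLIMATE_PREDICTORS)]
                   for i in range(n_adaptive)]
    driver_col = {v: k for k, v in enumerate(CLIMATE_PREDICTORS)}

    # per-individual frequency matrix
    freq = pA[island_idx, :]  # (n_ind, n_loci)
    for j, drv in enumerate(drivers):
        col = n_neutral + j
        logit0 = np.log(p0[col] / (1 - p0[col]))
        freq[:, col] = 1.0 / (1.0 + np.exp(-(logit0 + effect_b * z[:, driver_col[drv]])))

    q = np.ones(n_ind)  # pool-A ancestry fraction
    if admixture_spec:
        mix = sample_meta["island"].map(
            lambda s: admixture_spec.get(s, 0.0)
        ).to_numpy(float)
        # per-individual pool-B fraction around the island rate
        q = 1.0 - np.clip(rng.beta(
            np.maximum(mix * 10, 1e-3), np.maximum((1 - mix) * 10, 1e-3)
        ), 0, 1)
        freq = q[:, None] * freq + (1 - q[:, None]) * pB[None, :]

    dosage = rng.binomial(2, np.clip(freq, 1e-9, 1 - 1e-9)).astype(np.int8)

    depth = None
    if depth_missingness:
        depth = rng.poisson(mean_depth, size=dosage.shape)
        dosage[depth < 5] = MISSING
    elif missing_rate > 0:
        dosage[rng.uniform(size=dosage.shape) < missing_rate] = MISSING

    snp_meta = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, n_loci + 1) * 1000,
        "ref": "A",
        "alt": "T",
        "mean_depth": (np.full(n_loci, mean_depth) if depth is None
                       else depth.mean(0)),
    })
    gm = GenotypeMatrix(dosage, snp_meta, sample_meta)
    if depth is not None:
        gm.depth = depth  # type: ignore[attr-defined]

    loci = pd.DataFrame({
        "locus": [f"snp{i}" for i in range(n_loci)],
        "label": ["neutral"] * n_neutral + ["adaptive"] * n_adaptive,
        "driver": [""] * n_neutral + drivers,
        "effect_b": [0.0] * n_neutral + [effect_b] * n_adaptive,
    })
    return gm, SimTruth(loci=loci, fst=fst, admixture=q)


def write_fixture(
    gm: GenotypeMatrix,
    arch: Archipelago,
    truth: SimTruth,
    out_dir: str | Path,
    seed: int,
    overwrite: bool = False,
) -> dict:
    """Emit VCF + CSVs (samples, climate, truth) and a JSON manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} exists and is not empty; pass overwrite=True to replace"
        )
    out.mkdir(parents=True, exist_ok=True)

    depth = getattr(gm, "depth", None)
    write_vcf(gm, out / "genotypes.vcf", depth=depth)
    gm.sample_meta.to_csv(out / "samples.csv", index=False)

    grid = arch.grid.set_index("cell_id")
    clim = grid.loc[gm.sample_meta["cell_id"], CLIMATE_PREDICTORS].reset_index()
    clim.insert(0, "sample_id", gm.sample_meta["id"].to_numpy())
    clim.to_csv(out / "climate_samples.csv", index=False)

    g = pd.concat([
        arch.grid.assign(slice="historic"),
        arch.future.assign(slice="future"),
    ])
    g.to_csv(out / "climate_grid.csv", index=False)
    truth.loci.to_csv(out / "truth.csv", index=False)

    manifest = {
        "seed": seed,
        "files": ["genotypes.vcf", "samples.csv", "climate_samples.csv",
                  "climate_grid.csv", "truth.csv"],
        "n_samples": gm.n_samples,
        "n_snps": gm.n_snps,
        "fst": truth.fst,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
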