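"""Genotype and climate I/O plus the standard site/genotype filter ladder.

The central container is :class:`GenotypeMatrix`: an individuals x SNPs
dosage matrix (0/1/2, ``-1`` = missing) carrying per-SNP and per-sample
metadata.  Filtering follows the usual short-read hygiene sequence for
population-genomic SNP panels: keep biallelic SNPs, drop low-mean-depth
sites, mask low-depth genotypes, drop low-MAF and high-missingness sites,
then LD-prune with a sliding window and mode-impute the remainder for
ordination methods that need complete data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: canonical climate predictor columns used throughout the pipeline
CLIMATE_PREDICTORS = ["BIO5", "BIO6", "BIO15", "BIO18", "BIO19", "elev"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix with aligned SNP and sample metadata.

    Attributes
    ----------
    dosage : ndarray of int8, shape (n_samples, n_snps)
        Counts of the alternate allele; ``-1`` marks a missing genotype.
    snp_meta : DataFrame with columns chrom, pos, ref, alt, mean_depth
        Positions are 1-based and strictly increasing within a chromosome.
    sample_meta : DataFrame with at least a sample id column
        Typically id, island, lat, lon, species_field_id.
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x SNPs)")
        if len(self.snp_meta) != self.dosage.shape[1]:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows for "
                f"{self.dosage.shape[1]} dosage columns"
            )
        if len(self.sample_meta) != self.dosage.shape[0]:
            raise ValueError(
                f"sample_meta has {len(self.sample_meta)} rows for "
                f"{self.dosage.shape[0]} dosage rows"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosage[:, idx],
            self.snp_meta.iloc[idx].reset_index(drop=True),
            self.sample_meta,
        )

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing genotypes."""
        d = self.dosage
        ok = d != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(ok, d, 0).sum(0) / (2.0 * ok.sum(0))

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class FilterReport:
    """Ledger of the site-filter ladder; input = output + sum(removed)."""

    n_input: int
    n_output: int
    removed: dict = field(default_factory=dict)
    genotypes_masked_by_depth: int = 0

    def __post_init__(self) -> None:
        total = sum(self.removed.values())
        if self.n_input - total != self.n_output:
            raise ValueError(
                f"filter ledger does not balance: {self.n_input} input, "
                f"{total} removed, {self.n_output} output"
            )
        if any(v < 0 for v in self.removed.values()):
            raise ValueError("negative removal count")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_output": self.n_output,
                "removed": self.removed,
                "genotypes_masked_by_depth": self.genotypes_masked_by_depth,
            },
            indent=2,
        )


def read_vcf(path: str, min_gt_depth: int = 5) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Genotypes whose FORMAT/DP is below ``min_gt_depth`` are set to missing
    (the low-depth genotype mask).  Multiallelic or non-SNP records are
    excluded.  Per-SNP mean depth is recorded from the *unmasked* DP values
    so the site mean-depth filter sees raw coverage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_masked = 0
    n_non_biallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_non_biallelic += 1
            continue  # not a biallelic SNP
        gt = rec.gt_types.astype(np.int8)  # 0/1/2, 3 = unknown
        gt[gt == 3] = MISSING
        dp = rec.format("DP")
        if dp is None:
            if min_gt_depth > 0:
                raise ValueError(
                    f"record {rec.CHROM}:{rec.POS} lacks FORMAT/DP but "
                    f"min_gt_depth={min_gt_depth} > 0"
                )
            mean_depth = np.nan
        else:
            dp = dp.reshape(-1).astype(float)
            dp[dp < 0] = np.nan  # cyvcf2 encodes missing DP as negative
            mean_depth = float(np.nanmean(dp)) if np.isfinite(dp).any() else np.nan
            if min_gt_depth > 0:
                low = np.nan_to_num(dp, nan=-1.0) < min_gt_depth
                n_masked += int((low & (gt != MISSING)).sum())
                gt[low] = MISSING
        rows.append(gt)
        meta.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], mean_depth))
    if not rows:
        raise ValueError(f"no biallelic SNP records found in {path}")
    dosage = np.stack(rows, axis=1)
    snp_meta = pd.DataFrame(
        meta, columns=["chrom", "pos", "ref", "alt", "mean_depth"]
    )
    sample_meta = pd.DataFrame({"id": samples})
    gm = GenotypeMatrix(dosage, snp_meta, sample_meta)
    gm.n_genotypes_depth_masked = n_masked  # type: ignore[attr-defined]
    gm.n_non_biallelic = n_non_biallelic  # type: ignore[attr-defined]
    return gm


def attach_sample_meta(gm: GenotypeMatrix, table: pd.DataFrame,
                       id_col: str = "sample_id") -> GenotypeMatrix:
    """Join a metadata table onto the matrix's samples, preserving order."""
    t = table.set_index(id_col)
    missing = [s for s in gm.sample_meta["id"] if s not in t.index]
    if missing:
        raise KeyError(f"samples absent from metadata table: {missing[:5]}")
    merged = t.loc[gm.sample_meta["id"]].reset_index().rename(
        columns={id_col: "id"}
    )
    return replace(gm, sample_meta=merged)


def filter_sites(
    gm: GenotypeMatrix,
    min_mean_depth: float = 5.0,
    min_maf: float = 0.01,
    max_missing: float = 0.10,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the site-filter ladder: mean depth, MAF, missingness (in order).

    MAF and missingness are computed on the current (depth-masked) dosages.
    Raises if every SNP is removed.
    """
    if not (0 <= min_maf < 0.5):
        raise ValueError("min_maf must be in [0, 0.5)")
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must be in [0, 1]")
    n_bad = getattr(gm, "n_non_biallelic", 0)
    n_in = gm.n_snps + n_bad
    removed: dict[str, int] = {"non_biallelic": n_bad}

    md = gm.snp_meta["mean_depth"].to_numpy(dtype=float)
    keep = ~(md < min_mean_depth)  # NaN mean depth passes (no DP data)
    removed["mean_depth"] = int((~keep).sum())
    gm = gm.take_snps(np.where(keep)[0])

    maf = gm.maf()
    keep = ~(np.nan_to_num(maf, nan=0.0) < min_maf)
    removed["maf"] = int((~keep).sum())
    gm = gm.take_snps(np.where(keep)[0])

    miss_frac = gm.missing_mask().mean(0)
    keep = miss_frac <= max_missing
    removed["missingness"] = int((~keep).sum())
    gm = gm.take_snps(np.where(keep)[0])

    if gm.n_snps == 0:
        raise ValueError("all SNPs removed: empty matrix after filtering")
    report = FilterReport(
        n_input=n_in,
        n_output=gm.n_snps,
        removed=removed,
        genotypes_masked_by_depth=getattr(gm, "n_genotypes_depth_masked", 0),
    )
    return gm, report


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete entries.

    Returns NaN when either column is constant on the shared entries
    (undefined correlation) or fewer than 2 entries are shared.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return np.nan
    c = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(c * c / (vx * vy))


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2: float = 0.1,
    dialect: str = "low-maf",
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Sliding-window LD pruning of dosage columns.

    Within each window of ``window`` variants (advancing by ``step``, per
    chromosome), pairs of retained SNPs with squared pairwise-complete
    Pearson correlation above ``r2`` are broken by dropping one SNP until no
    offending pair remains.  ``dialect='low-maf'`` drops the lower-MAF SNP
    of the pair (tie: the later position); ``'keep-first'`` always drops the
    later SNP.  Returns the pruned matrix and the kept column indices.
    """
    if not window > step >= 1:
        raise ValueError("require window > step >= 1")
    if dialect not in ("low-maf", "keep-first"):
        raise ValueError(f"unknown prune dialect {dialect!r}")
    maf = gm.maf()
    keep = np.ones(gm.n_snps, dtype=bool)
    chroms = gm.snp_meta["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.where(chroms == chrom)[0]
        start = 0
        while start < len(cols):
            win = cols[start:start + window]
            live = [c for c in win if keep[c]]
            # greedy removal until no pair in this window exceeds r2
            changed = True
            while changed:
                changed = False
                out = None
                for ai in range(len(live)):
                    for bi in range(ai + 1, len(live)):
                        a, b = live[ai], live[bi]
                        r2ab = _pairwise_r2(gm.dosage[:, a], gm.dosage[:, b])
                        if np.isfinite(r2ab) and r2ab > r2:
                            if dialect == "keep-first":
                                out = b
                            elif maf[a] < maf[b]:
                                out = a
                            elif maf[b] < maf[a]:
                                out = b
                            else:
                                out = b  # MAF tie: drop later position
                            break
                    if out is not None:
                        break
                if out is not None:
                    keep[out] = False
                    live.remove(out)
                    changed = True
            start += step
    kept_idx = np.where(keep)[0]
    return gm.take_snps(kept_idx), kept_idx


def impute_mode(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing genotypes with each SNP's modal dosage.

    Mode ties break toward the lower dosage (deterministic, slightly
    reference-biased).  A SNP with no observed genotype is an error.
    """
    d = gm.dosage.copy()
    miss = d == MISSING
    if not miss.any():
        return gm
    for j in np.where(miss.any(0))[0]:
        col = d[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            meta = gm.snp_meta.iloc[j]
            raise ValueError(
                f"SNP {meta['chrom']}:{meta['pos']} has no observed genotypes"
            )
        counts = np.bincount(obs, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the lowest on ties
        col[col == MISSING] = mode
    return replace(gm, dosage=d)


def select_uncorrelated_predictors(
    climate: pd.DataFrame, threshold: float = 0.7
) -> list[str]:
    """Greedily reduce predictors until all pairwise |r| <= threshold.

    Constant columns are removed first (their correlation is undefined).
    At each step the worst-offending pair is found and, of the two, the
    predictor with the larger mean |r| to all other retained predictors is
    eliminated.
    """
    cols = list(climate.columns)
    if len(cols) < 2:
        raise ValueError("need at least two predictors")
    const = [c for c in cols if np.nanstd(climate[c].to_numpy(float)) == 0]
    if const:
        warnings.warn(f"dropping constant predictors: {const}")
        cols = [c for c in cols if c not in const]
    while len(cols) > 1:
        r = climate[cols].corr().abs().to_numpy()
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        if r[i, j] <= threshold:
            break
        mean_i = r[i].sum() / (len(cols) - 1)
        mean_j = r[j].sum() / (len(cols) - 1)
        drop = cols[i] if mean_i >= mean_j else cols[j]
        cols.remove(drop)
    return cols


def read_climate_table(path: str) -> pd.DataFrame:
    """Per-sample climate CSV (sample_id + predictor columns)."""
    return pd.read_csv(path)


def read_climate_grid(path: str) -> pd.DataFrame:
    """Gridded climate CSV: cell_id, x, y, island, slice, predictors."""
    df = pd.read_csv(path)
    required = {"cell_id", "x", "y", "slice"}
    if not required.issubset(df.columns):
        raise ValueError(f"grid CSV must contain columns {sorted(required)}")
    return df


def write_vcf(gm: GenotypeMatrix, path: str, depth: np.ndarray | None = None) -> None:
    """Write the matrix as a plain-text VCF 4.2 with GT and FORMAT/DP.

    ``depth`` is an optional per-genotype depth array (samples x SNPs);
    without it every called genotype gets a constant DP of 20.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    ids = list(gm.sample_meta["id"].astype(str))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(gm.snp_meta["chrom"]):
            sub = gm.snp_meta[gm.snp_meta["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for j in range(gm.n_snps):
            m = gm.snp_meta.iloc[j]
            fields = [
                str(m["chrom"]), str(int(m["pos"])), f"snp{j}",
                str(m["ref"]), str(m["alt"]), ".", "PASS", ".", "GT:DP",
            ]
            for i in range(gm.n_samples):
                g = int(gm.dosage[i, j])
                dp = 20 if depth is None else int(depth[i, j])
                fields.append(f"{gt_str[g]}:{dp}")
            fh.write("\t".join(fields) + "\n")
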