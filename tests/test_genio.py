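"""VCF reading, the site/genotype filter ladder, LD pruning, imputation
and predictor-collinearity reduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from archoffset import genio
from archoffset.genio import MISSING

from conftest import make_gm

VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""


def write_vcf_text(tmp_path, records):
    p = tmp_path / "toy.vcf"
    p.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
    return p


class TestReadVcf:
    def test_low_depth_genotype_masked(self, tmp_path):
        p = write_vcf_text(tmp_path, [
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:4\t1/1:9\t0/0:30",
        ])
        gm = genio.read_vcf(p, min_gt_depth=5)
        assert gm.dosage[0, 0] == MISSING
        assert gm.dosage[1, 0] == 2 and gm.dosage[2, 0] == 0

    def test_depth_filter_disabled_keeps_raw_gt(self, tmp_path):
        p = write_vcf_text(tmp_path, [
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:1\t1/1:2\t./.:30",
        ])
        gm = genio.read_vcf(p, min_gt_depth=0)
        assert list(gm.dosage[:, 0]) == [1, 2, MISSING]

    def test_triallelic_record_excluded(self, tmp_path):
        p = write_vcf_text(tmp_path, [
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t1/1:9",
            "chr1\t200\t.\tA\tT,G\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t1/2:9",
            "chr1\t300\t.\tC\tG\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t1/1:9",
        ])
        gm = genio.read_vcf(p, min_gt_depth=5)
        assert gm.n_snps == 2
        assert gm.n_non_biallelic == 1
        assert list(gm.snp_meta["pos"]) == [100, 300]

    def test_mean_depth_recorded_from_raw_dp(self, tmp_path):
        p = write_vcf_text(tmp_path, [
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:2\t1/1:4\t0/0:6",
        ])
        gm = genio.read_vcf(p, min_gt_depth=5)
        assert gm.snp_meta["mean_depth"].iloc[0] == pytest.approx(4.0)


class TestFilterSites:
    def toy(self):
        # 20 samples x 10 SNPs: columns 0-5 clean, 6-7 low MAF,
        # 8 high missingness (3/20 = 15%), 9 low mean depth
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        d[:, 6] = 0
        d[0, 6] = 1          # single het: MAF 1/40 = 0.025
        d[:, 7] = 0          # monomorphic, MAF 0
        d[:5, 0] = 1         # keep col 0 polymorphic
        d[0:3, 8] = MISSING  # 15% missing
        gm = make_gm(d)
        gm.snp_meta.loc[6, "mean_depth"] = 20.0
        gm.snp_meta.loc[9, "mean_depth"] = 2.0
        return gm

    def test_toy_ladder_counts(self):
        gm = self.toy()
        # min_maf=0.05 puts the single-het column below the MAF threshold
        out, rep = genio.filter_sites(gm, min_mean_depth=5, min_maf=0.05,
                                      max_missing=0.10)
        assert rep.removed["mean_depth"] == 1
        assert rep.removed["maf"] == 2
        assert rep.removed["missingness"] == 1
        assert out.n_snps == 6
        assert rep.n_input - sum(rep.removed.values()) == rep.n_output

    def test_monomorphic_removed(self):
        d = np.zeros((10, 2), dtype=np.int8)
        d[:5, 0] = 2
        gm = make_gm(d)
        out, rep = genio.filter_sites(gm)
        assert out.n_snps == 1
        assert rep.removed["maf"] == 1

    def test_high_missingness_removed(self):
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, size=(20, 4)).astype(np.int8)
        d[:3, 1] = MISSING  # 15% > 10%
        out, rep = genio.filter_sites(make_gm(d))
        assert rep.removed["missingness"] == 1
        assert out.n_snps == 3

    def test_empty_result_is_error(self):
        d = np.zeros((6, 3), dtype=np.int8)  # all monomorphic
        with pytest.raises(ValueError, match="empty matrix"):
            genio.filter_sites(make_gm(d))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_ledger_always_balances(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.choice([0, 1, 2, MISSING], size=(12, 30),
                       p=[0.4, 0.3, 0.2, 0.1]).astype(np.int8)
        gm = make_gm(d)
        gm.snp_meta["mean_depth"] = rng.uniform(2, 30, 30)
        try:
            out, rep = genio.filter_sites(gm)
        except ValueError:
            return  # everything removed is a legal outcome
        assert rep.n_input == rep.n_output + sum(rep.removed.values())


def brute_force_prune(dosage, maf, window, step, r2):
    """Independent re-statement of the window/removal rule with plain loops."""
    n_snps = dosage.shape[1]
    keep = set(range(n_snps))
    start = 0
    while start < n_snps:
        live = [j for j in range(start, min(start + window, n_snps))
                if j in keep]
        while True:
            removed = None
            for ai in range(len(live)):
                for bi in range(ai + 1, len(live)):
                    a, b = live[ai], live[bi]
                    xa, xb = dosage[:, a], dosage[:, b]
                    ok = (xa != MISSING) & (xb != MISSING)
                    if ok.sum() < 2:
                        continue
                    va = np.var(xa[ok].astype(float))
                    vb = np.var(xb[ok].astype(float))
                    if va == 0 or vb == 0:
                        continue
                    r = np.corrcoef(xa[ok], xb[ok])[0, 1]
                    if r * r > r2:
                        if maf[a] < maf[b]:
                            removed = a
                        elif maf[b] < maf[a]:
                            removed = b
                        else:
                            removed = b
                        break
                if removed is not None:
                    break
            if removed is None:
                break
            keep.discard(removed)
            live.remove(removed)
        start += step
    return sorted(keep)


class TestLdPrune:
    def test_identical_columns_keep_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, 50).astype(np.int8)
        d = np.column_stack([col, col, rng.integers(0, 3, 50)]).astype(np.int8)
        _, kept = genio.ld_prune(make_gm(d), window=3, step=1, r2=0.1)
        assert sum(1 for k in kept if k in (0, 1)) == 1

    def test_orthogonal_columns_all_retained(self):
        # constructed so every pairwise correlation is exactly zero
        base = np.array([
            [0, 0, 0, 0], [0, 0, 2, 2], [2, 2, 0, 0], [2, 2, 2, 2],
            [0, 2, 0, 2], [2, 0, 2, 0], [0, 2, 2, 0], [2, 0, 0, 2],
        ], dtype=np.int8)
        r = np.corrcoef(base.T)
        assert np.allclose(r - np.eye(4), 0)
        _, kept = genio.ld_prune(make_gm(base), window=4, step=1, r2=0.1)
        assert list(kept) == [0, 1, 2, 3]

    def test_matches_brute_force_oracle_on_planted_blocks(self):
        rng = np.random.default_rng(42)
        n, m = 80, 100
        d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        # plant correlated blocks: copies with sprinkled noise
        for block in ([5, 6, 7], [20, 21], [50, 51, 52, 53], [90, 99]):
            src = d[:, block[0]].copy()
            for j in block[1:]:
                col = src.copy()
                flip = rng.random(n) < 0.05
                col[flip] = rng.integers(0, 3, flip.sum())
                d[:, j] = col
        gm = make_gm(d)
        _, kept = genio.ld_prune(gm, window=50, step=10, r2=0.1)
        oracle = brute_force_prune(d, gm.maf(), window=50, step=10, r2=0.1)
        assert list(kept) == oracle

    def test_idempotent(self):
        # window spans the whole panel so both passes compare every pair
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(60, 40)).astype(np.int8)
        d[:, 10] = d[:, 11]
        pruned, kept = genio.ld_prune(make_gm(d), window=50, step=5, r2=0.1)
        again, kept2 = genio.ld_prune(pruned, window=50, step=5, r2=0.1)
        assert len(kept2) == pruned.n_snps

    def test_keep_first_dialect(self):
        col = np.array([0, 1, 2] * 10, dtype=np.int8)
        other = col.copy()
        d = np.column_stack([col, other])
        _, kept = genio.ld_prune(make_gm(d), window=2, step=1, r2=0.1,
                                 dialect="keep-first")
        assert list(kept) == [0]

    def test_window_step_validation(self):
        d = np.zeros((4, 4), dtype=np.int8)
        with pytest.raises(ValueError, match="window > step"):
            genio.ld_prune(make_gm(d), window=5, step=5)


class TestImputeMode:
    def test_mode_fill(self):
        d = np.array([[0], [0], [1], [MISSING]], dtype=np.int8)
        out = genio.impute_mode(make_gm(d))
        assert out.dosage[3, 0] == 0

    def test_tie_goes_to_lower_dosage(self):
        d = np.array([[0], [0], [2], [2], [MISSING]], dtype=np.int8)
        out = genio.impute_mode(make_gm(d))
        assert out.dosage[4, 0] == 0

    def test_no_missing_identity(self):
        d = np.array([[0, 1], [2, 1]], dtype=np.int8)
        gm = make_gm(d)
        out = genio.impute_mode(gm)
        assert out is gm

    def test_preserves_observed_entries(self):
        rng = np.random.default_rng(5)
        d = rng.choice([0, 1, 2, MISSING], size=(30, 20),
                       p=[0.3, 0.3, 0.3, 0.1]).astype(np.int8)
        d[0, :] = 1  # guarantee every SNP observed at least once
        out = genio.impute_mode(make_gm(d))
        obs = d != MISSING
        np.testing.assert_array_equal(out.dosage[obs], d[obs])
        assert not (out.dosage == MISSING).any()

    def test_all_missing_snp_is_error(self):
        d = np.full((4, 1), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="no observed genotypes"):
            genio.impute_mode(make_gm(d))


class TestSelectUncorrelatedPredictors:
    def test_near_duplicate_pair_reduced(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=200)
        df = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.01, 200),
                           "c": rng.normal(size=200)})
        kept = genio.select_uncorrelated_predictors(df, threshold=0.7)
        assert "c" in kept and len(kept) == 2

    def test_compliant_set_untouched(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(300, 6)),
                          columns=list("abcdef"))
        kept = genio.select_uncorrelated_predictors(df, threshold=0.7)
        assert kept == list("abcdef")

    def test_matches_greedy_oracle_on_constructed_table(self):
        rng = np.random.default_rng(9)
        z1, z2 = rng.normal(size=200), rng.normal(size=200)
        df = pd.DataFrame({
            "p1": z1,
            "p2": z1 + rng.normal(0, 0.3, 200),
            "p3": z1 + rng.normal(0, 0.5, 200),
            "p4": z2,
            "p5": z2 + rng.normal(0, 0.2, 200),
            "p6": rng.normal(size=200),
            "p7": z1 - z2 + rng.normal(0, 0.3, 200),
            "p8": rng.normal(size=200),
        })

        # independent restatement of the stated greedy rule
        cols = list(df.columns)
        while True:
            r = df[cols].corr().abs()
            worst, pair = 0.0, None
            for i, a in enumerate(cols):
                for b in cols[i + 1:]:
                    if r.loc[a, b] > worst:
                        worst, pair = r.loc[a, b], (a, b)
            if worst <= 0.7:
                break
            a, b = pair
            ma = np.mean([r.loc[a, c] for c in cols if c != a])
            mb = np.mean([r.loc[b, c] for c in cols if c != b])
            cols.remove(a if ma >= mb else b)

        kept = genio.select_uncorrelated_predictors(df, threshold=0.7)
        assert kept == cols
        assert (df[kept].corr().abs().to_numpy()
                - np.eye(len(kept)) <= 0.7 + 1e-12).all()

    def test_constant_predictor_warns_and_drops(self):
        df = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0),
                           "c": np.arange(50.0) ** 2})
        with pytest.warns(UserWarning, match="constant"):
            kept = genio.select_uncorrelated_predictors(df, threshold=0.99)
        assert "a" not in kept
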