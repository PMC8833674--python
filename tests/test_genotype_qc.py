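import numpy as np
import pandas as pd
import pytest

from conftest import hwe_genotypes, make_genotypes
from geno2lnc.datatypes import DataError
from geno2lnc.genotype_qc import (
    depth_exclude_genetic,
    genetic_pca,
    ibd_kinship,
    ld_prune,
    relatedness_prune,
    snp_sample_filter,
)


class TestSnpSampleFilter:
    def test_maf_counting_one_in_ten_alleles(self):
        g = make_genotypes(np.array([[0.0], [0.0], [0.0], [0.0], [1.0]]))
        assert g.maf().iloc[0] == pytest.approx(0.1)
        filtered, _ = snp_sample_filter(g, maf_min=0.01, snp_callrate_min=0.0,
                                        sample_callrate_min=0.0)
        assert len(filtered.snp_ids) == 1

    def test_monomorphic_snp_removed(self, rng):
        dos = rng.binomial(2, 0.3, size=(20, 3)).astype(float)
        dos[:, 1] = 0.0
        g = make_genotypes(dos)
        filtered, report = snp_sample_filter(g)
        assert g.snp_ids[1] in report.snps_removed_maf
        assert g.snp_ids[1] not in filtered.snp_ids

    def test_sample_missing_six_percent_removed(self, rng):
        dos = rng.binomial(2, 0.4, size=(10, 100)).astype(float)
        dos[0, :6] = np.nan  # 6% missing
        g = make_genotypes(dos)
        filtered, report = snp_sample_filter(g, snp_callrate_min=0.0)
        assert g.sample_ids[0] in report.samples_removed_callrate
        assert len(filtered.sample_ids) == 9

    def test_snp_filter_runs_before_sample_filter(self, rng):
        # sample 0 misses calls only on low-MAF SNPs: once those SNPs are
        # dropped, its call rate is 1 and it must be kept
        dos = rng.binomial(2, 0.4, size=(10, 50)).astype(float)
        dos[:, :10] = 0.0  # monomorphic -> removed by MAF
        dos[0, :10] = np.nan
        g = make_genotypes(dos)
        filtered, _ = snp_sample_filter(g)
        assert g.sample_ids[0] in filtered.sample_ids

    def test_idempotent(self, rng):
        g = hwe_genotypes(rng, 30, 80)
        once, _ = snp_sample_filter(g)
        twice, _ = snp_sample_filter(once)
        assert list(once.snp_ids) == list(twice.snp_ids)
        assert list(once.sample_ids) == list(twice.sample_ids)


class TestIbdKinship:
    def _with_relatives(self, rng, m=3000):
        p = rng.uniform(0.2, 0.5, m)
        dos = rng.binomial(2, p, size=(12, m)).astype(float)
        dos[1] = dos[0]  # duplicate pair (0, 1)
        transmitted = rng.binomial(1, dos[2] / 2.0)
        dos[3] = transmitted + rng.binomial(1, p)  # parent-offspring (2, 3)
        return make_genotypes(dos)

    def test_duplicate_unrelated_parent_offspring(self, rng):
        g = self._with_relatives(rng)
        kin = ibd_kinship(g)
        c = kin.coefficients
        assert 0.95 <= c.iloc[0, 1] <= 1.0
        assert 0.4 <= c.iloc[2, 3] <= 0.6
        unrelated = [
            c.iloc[i, j]
            for i in range(12)
            for j in range(i + 1, 12)
            if (i, j) not in [(0, 1), (2, 3)]
        ]
        assert max(unrelated) <= 0.1

    def test_symmetric_and_self_one(self, rng):
        g = hwe_genotypes(rng, 8, 500)
        kin = ibd_kinship(g)
        c = kin.coefficients.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)

    def test_snp_order_invariance(self, rng):
        g = self._with_relatives(rng, m=1000)
        perm = rng.permutation(len(g.snp_ids))
        g2 = g.subset(snps=g.snp_ids[perm])
        pd.testing.assert_frame_equal(
            ibd_kinship(g).coefficients, ibd_kinship(g2).coefficients
        )

    def test_warns_on_few_snps(self, rng):
        g = hwe_genotypes(rng, 5, 50)
        with pytest.warns(UserWarning, match="recommended"):
            ibd_kinship(g)

    def test_sparse_pair_flagged_unreliable(self, rng):
        dos = rng.binomial(2, 0.3, size=(4, 200)).astype(float)
        dos[0, 40:] = np.nan
        dos[1, :160] = np.nan  # pair (0, 1) share only 0 complete SNPs
        g = make_genotypes(dos)
        kin = ibd_kinship(g)
        assert (g.sample_ids[0], g.sample_ids[1]) in kin.unreliable_pairs


class TestRelatednessPrune:
    def _kin(self, ids, pairs):
        c = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
        np.fill_diagonal(c.to_numpy(), 1.0)
        for a, b, v in pairs:
            c.loc[a, b] = c.loc[b, a] = v
        from geno2lnc.genotype_qc import KinshipEstimate

        return KinshipEstimate(coefficients=c)

    def test_lower_call_rate_member_removed(self, rng):
        dos = rng.binomial(2, 0.3, size=(4, 100)).astype(float)
        dos[1, :3] = np.nan  # S001 call rate 0.97; S000 at 0.99
        dos[0, 0] = np.nan
        g = make_genotypes(dos)
        kin = self._kin(list(g.sample_ids), [("S000", "S001", 0.9)])
        kept = relatedness_prune(kin, g)
        assert "S001" not in kept and "S000" in kept

    def test_no_pair_above_threshold_noop(self, rng):
        g = hwe_genotypes(rng, 5, 100)
        kin = self._kin(list(g.sample_ids), [("S000", "S001", 0.05)])
        assert len(relatedness_prune(kin, g)) == 5

    def test_clique_of_three_removes_two(self, rng):
        dos = rng.binomial(2, 0.3, size=(5, 100)).astype(float)
        dos[0, :2] = np.nan  # S000 lowest call rate
        dos[1, :1] = np.nan  # S001 middle
        g = make_genotypes(dos)
        kin = self._kin(
            list(g.sample_ids),
            [("S000", "S001", 0.5), ("S000", "S002", 0.5), ("S001", "S002", 0.5)],
        )
        kept = relatedness_prune(kin, g)
        assert set(kept) == {"S002", "S003", "S004"}

    def test_result_has_no_pair_above_threshold(self, rng):
        g = hwe_genotypes(rng, 8, 100)
        pairs = [("S000", "S001", 0.4), ("S001", "S002", 0.3), ("S004", "S005", 0.2)]
        kin = self._kin(list(g.sample_ids), pairs)
        kept = set(relatedness_prune(kin, g, threshold=0.1))
        for a, b, v in pairs:
            if v > 0.1:
                assert not ({a, b} <= kept)


class TestLdPrune:
    def test_identical_snps_keep_exactly_one(self, rng):
        base = rng.binomial(2, 0.4, size=30).astype(float)
        g = make_genotypes(np.column_stack([base, base]))
        kept = ld_prune(g)
        assert len(kept) == 1

    def test_independent_snps_all_kept(self, rng):
        g = hwe_genotypes(rng, 500, 40)
        kept = ld_prune(g, r2_max=0.1)
        assert len(kept) == 40

    def test_five_snp_fixture_matches_brute_force(self, rng):
        # two tight LD blocks {0,1,2} and {3,4}
        n = 200
        a = rng.binomial(2, 0.45, size=n).astype(float)
        b = rng.binomial(2, 0.35, size=n).astype(float)
        flip = rng.random(n) < 0.05

        def noisy(v):
            out = v.copy()
            swap = rng.random(n) < 0.03
            out[swap] = rng.binomial(2, 0.5, swap.sum())
            return out

        dos = np.column_stack([a, noisy(a), noisy(a), b, noisy(b)])
        g = make_genotypes(dos)
        kept = ld_prune(g, r2_max=0.1, window=5)
        corr = np.corrcoef(dos.T) ** 2
        idx = {s: i for i, s in enumerate(g.snp_ids)}
        for x in kept:
            for y in kept:
                if x != y:
                    assert corr[idx[x], idx[y]] <= 0.1
        assert len(kept) == 2  # one survivor per block

    def test_no_surviving_pair_above_threshold(self, rng):
        # window spans every SNP, so the within-window guarantee is global
        n, m = 150, 30
        base = rng.binomial(2, 0.4, size=(n, 6)).astype(float)
        cols = [base[:, i % 6] for i in range(m)]
        g = make_genotypes(np.column_stack(cols))
        kept = ld_prune(g, r2_max=0.1, window=m, step=5)
        assert len(kept) == 6  # one survivor per duplicated block
        dos = g.dosages[list(kept)].to_numpy()
        corr = np.corrcoef(dos.T) ** 2
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert corr[i, j] <= 0.1 + 1e-9

    def test_deterministic(self, rng):
        g = hwe_genotypes(rng, 100, 60)
        assert list(ld_prune(g)) == list(ld_prune(g))


class TestGeneticPca:
    def test_two_subpops_separated_by_pc1(self, rng):
        m = 400
        p1 = rng.uniform(0.1, 0.5, m)
        shift = rng.normal(0, 0.12, m)
        p2 = np.clip(p1 + shift, 0.02, 0.98)
        dos = np.vstack(
            [rng.binomial(2, p1, size=(40, m)), rng.binomial(2, p2, size=(40, m))]
        ).astype(float)
        g = make_genotypes(dos)
        pcs = genetic_pca(g, k=5)
        labels = np.repeat([0, 1], 40)
        corr = np.corrcoef(pcs.scores["PC1"], labels)[0, 1]
        assert abs(corr) > 0.9

    def test_null_spectrum_within_marchenko_pastur_bulk(self, rng):
        n, m = 60, 1200
        g = hwe_genotypes(rng, n, m, maf=rng.uniform(0.1, 0.5, m))
        pcs = genetic_pca(g, k=10)
        edge = (1.0 + np.sqrt(n / m)) ** 2
        assert pcs.eigenvalues[0] < 1.5 * edge

    def test_duplicated_individuals_get_identical_scores(self, rng):
        dos = rng.binomial(2, 0.3, size=(20, 300)).astype(float)
        g = make_genotypes(np.vstack([dos, dos]))
        pcs = genetic_pca(g, k=4)
        assert np.allclose(
            pcs.scores.iloc[:20].to_numpy(), pcs.scores.iloc[20:].to_numpy(), atol=1e-8
        )

    def test_scores_centered_and_orthogonal(self, rng):
        g = hwe_genotypes(rng, 40, 200)
        pcs = genetic_pca(g, k=5)
        s = pcs.scores.to_numpy()
        assert np.allclose(s.mean(axis=0), 0.0, atol=1e-8)
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(gram))

    def test_k_too_large_errors(self, rng):
        g = hwe_genotypes(rng, 5, 50)
        with pytest.raises(DataError):
            genetic_pca(g, k=5)


class TestDepthExcludeGenetic:
    def test_98_to_93(self, rng):
        g = hwe_genotypes(rng, 98, 400)
        pcs = genetic_pca(g, k=10)
        assert len(depth_exclude_genetic(pcs, frac=0.05)) == 93

    def test_frac_zero_identity(self, rng):
        g = hwe_genotypes(rng, 30, 200)
        pcs = genetic_pca(g, k=5)
        assert len(depth_exclude_genetic(pcs, frac=0.0)) == 30

    def test_planted_outlier_excluded(self, rng):
        m = 500
        p = rng.uniform(0.2, 0.5, m)
        dos = rng.binomial(2, p, size=(40, m)).astype(float)
        p_out = np.clip(p + rng.normal(0, 0.3, m), 0.01, 0.99)
        dos[7] = rng.binomial(2, p_out)
        g = make_genotypes(dos)
        pcs = genetic_pca(g, k=5)
        kept = depth_exclude_genetic(pcs, frac=0.05)
        assert g.sample_ids[7] not in set(kept)
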