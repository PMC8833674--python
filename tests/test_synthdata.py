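import numpy as np
import pandas as pd
import pytest

from geno2lnc import synthdata as sd
from geno2lnc._robust import huber_rlm
from geno2lnc._vcf import read_vcf, write_vcf
from geno2lnc.datatypes import ConfigError, ExpressionMatrix, SampleCovariates
from geno2lnc.expression_prep import counts_to_log2tpm
from geno2lnc.genotype_qc import genetic_pca, ibd_kinship
from geno2lnc.impute_associate import associate, predict_expression
from geno2lnc.preselect import jt_permutation_test, trend_results_frame


class TestConfigValidation:
    def test_defaults_valid(self):
        sd.SimConfig().validate()

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_trend": 500, "n_transcripts": 100},
            {"maf_range": (0.0, 0.4)},
            {"maf_range": (0.1, 0.6)},
            {"target_r2": 1.2},
            {"true_or_per_log2": -1.0},
            {"nb_dispersion": -0.1},
            {"fst_like_divergence": -0.5},
            {"n_transcripts": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            sd.SimConfig(**kw).validate()


class TestTissueCounts:
    def test_byte_identical_given_seed(self):
        cfg = sd.SimConfig(seed=9, n_transcripts=40, n_trend=4)
        c1, t1 = sd.gen_tissue_counts(cfg)
        c2, t2 = sd.gen_tissue_counts(cfg)
        pd.testing.assert_frame_equal(c1.values, c2.values)
        assert t1.trend_transcript_ids == t2.trend_transcript_ids

    def test_both_trend_directions_planted(self):
        cfg = sd.SimConfig(seed=2, n_transcripts=50, n_trend=6)
        _, truth = sd.gen_tissue_counts(cfg)
        dirs = set(truth.trend_directions.values())
        assert dirs == {1, -1}

    def test_planted_trends_have_jt_power(self):
        cfg = sd.SimConfig(
            seed=4, n_per_stage=(30, 30, 30), n_transcripts=60, n_trend=10,
            trend_effect=1.0, nb_dispersion=0.3,
        )
        counts, truth = sd.gen_tissue_counts(cfg)
        expr = counts_to_log2tpm(counts)
        res = trend_results_frame(
            jt_permutation_test(expr, n_perm=499, seed=0)
        )
        planted = res.loc[truth.trend_transcript_ids]
        assert (planted["p_value"] < 0.05).mean() > 0.8

    def test_zero_effect_gives_null_pvalues(self):
        cfg = sd.SimConfig(seed=5, n_per_stage=(25, 25, 25), n_transcripts=80,
                           n_trend=20, trend_effect=0.0)
        counts, truth = sd.gen_tissue_counts(cfg)
        expr = counts_to_log2tpm(counts)
        res = trend_results_frame(jt_permutation_test(expr, n_perm=199, seed=0))
        planted = res.loc[truth.trend_transcript_ids]
        assert (planted["p_value"] < 0.05).mean() <= 0.15

    def test_too_many_trends_rejected(self):
        with pytest.raises(ConfigError):
            sd.gen_tissue_counts(sd.SimConfig(n_transcripts=5, n_trend=10))


class TestGenotypes:
    def test_empirical_maf_close_to_target(self):
        cfg = sd.SimConfig(seed=3, maf_range=(0.3, 0.3), n_snps=200)
        g = sd.gen_genotypes(cfg, n_individuals=600)
        maf = g.maf()
        assert (np.abs(maf - 0.3) < 0.03).mean() > 0.95

    def test_duplicate_individual_ibd_near_one(self):
        cfg = sd.SimConfig(seed=6, n_snps=2000)
        g = sd.gen_genotypes(cfg, n_individuals=20)
        dup = g.dosages.copy()
        dup.loc["TWIN"] = dup.iloc[0]
        g2 = sd.GenotypeMatrix(dup, g.snp_info) if hasattr(sd, "GenotypeMatrix") else None
        from geno2lnc.datatypes import GenotypeMatrix

        g2 = GenotypeMatrix(dup, g.snp_info)
        kin = ibd_kinship(g2)
        assert kin.coefficients.loc[g.sample_ids[0], "TWIN"] >= 0.95

    def test_two_subpops_separate_on_pc1(self):
        cfg = sd.SimConfig(seed=8, n_subpops=2, fst_like_divergence=0.1, n_snps=600)
        g = sd.gen_genotypes(cfg, n_individuals=80)
        pcs = genetic_pca(g, k=4)
        labels = g.subpop_labels.to_numpy()
        pc1 = pcs.scores["PC1"].to_numpy()
        # AUC of PC1 as a score for subpopulation membership
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(labels, pc1)
        assert max(auc, 1 - auc) > 0.9

    def test_vcf_round_trip_with_missing(self, tmp_path):
        cfg = sd.SimConfig(seed=1, n_snps=30)
        g = sd.gen_genotypes(cfg, n_individuals=12)
        g.dosages.iloc[2, 5] = np.nan
        path = tmp_path / "x.vcf"
        write_vcf(g, path)
        g2 = read_vcf(path)
        assert np.allclose(
            g.dosages.to_numpy(), g2.dosages.to_numpy(), equal_nan=True
        )
        assert list(g.snp_ids) == list(g2.snp_ids)
        assert list(g.sample_ids) == list(g2.sample_ids)

    def test_hwe_frequencies(self):
        cfg = sd.SimConfig(seed=2, maf_range=(0.4, 0.4), n_snps=100)
        g = sd.gen_genotypes(cfg, n_individuals=2000)
        het = (g.dosages == 1).mean(axis=0)
        assert abs(het.mean() - 2 * 0.4 * 0.6) < 0.01


def _planted_serum(seed=0, target_r2=0.26, n=93, **kw):
    cfg = sd.SimConfig(seed=seed, n_transcripts=30, n_trend=2, target_r2=target_r2,
                       n_individuals_eqtl=n, **kw)
    counts, truth = sd.gen_tissue_counts(cfg)
    g = sd.gen_genotypes(cfg, n_individuals=n)
    sd.assign_eqtls(cfg, truth, g)
    rng = np.random.default_rng(seed + 77)
    covars = sd.gen_covariates(n, rng, sample_ids=list(g.sample_ids), n_pcs=10)
    serum = sd.gen_serum_expression(g, truth, covars, cfg)
    return cfg, truth, g, covars, serum


class TestSerumExpression:
    def test_deterministic(self):
        _, _, _, _, s1 = _planted_serum(seed=3)
        _, _, _, _, s2 = _planted_serum(seed=3)
        pd.testing.assert_frame_equal(s1, s2)

    def test_zero_betas_unreachable_target(self):
        with pytest.raises(ConfigError, match="zero variance|unreachable"):
            _planted_serum(seed=1, eqtl_beta=0.0)

    def test_noiseless_limit_recovers_betas(self):
        # covariate effects must be off: at target_r2 -> 1 there is no noise
        # budget left for them
        cfg, truth, g, covars, serum = _planted_serum(
            seed=2, target_r2=0.999, age_beta=0.0, gender_beta=0.0
        )
        t = truth.trend_transcript_ids[0]
        entries = truth.eqtl_map[t]
        from geno2lnc.eqtl_validation import encode_penetrance

        X = np.column_stack(
            [np.ones(len(g.sample_ids))]
            + [
                encode_penetrance(g.dosages[s].to_numpy(), m)[:, 0]
                for s, m, _ in entries
            ]
            + [
                covars.table["age"].to_numpy() - covars.table["age"].mean(),
                covars.table["gender"].to_numpy(),
            ]
        )
        y = serum.loc[t].to_numpy()
        beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
        for k, (_, _, beta) in enumerate(entries):
            assert beta_hat[1 + k] == pytest.approx(beta, abs=0.05)

    def test_snp_variance_fraction_near_target(self):
        fracs = []
        for seed in range(25):
            cfg, truth, g, covars, serum = _planted_serum(seed=seed, target_r2=0.26)
            t = truth.trend_transcript_ids[0]
            from geno2lnc.eqtl_validation import encode_penetrance

            signal = np.zeros(len(g.sample_ids))
            for s, m, b in truth.eqtl_map[t]:
                signal += b * encode_penetrance(g.dosages[s].to_numpy(), m)[:, 0]
            fracs.append(np.var(signal) / np.var(serum.loc[t].to_numpy()))
        assert abs(np.mean(fracs) - 0.26) < 0.05

    def test_flat_serum_rows_present_in_full_matrix(self):
        cfg = sd.SimConfig(seed=4, n_transcripts=40, n_trend=2)
        counts, truth = sd.gen_tissue_counts(cfg)
        g = sd.gen_genotypes(cfg)
        sd.assign_eqtls(cfg, truth, g)
        covars = sd.gen_covariates(
            len(g.sample_ids), np.random.default_rng(0), sample_ids=list(g.sample_ids)
        )
        serum = sd.gen_serum_matrix(g, truth, covars, cfg, list(counts.transcript_ids))
        mad = ExpressionMatrix(serum).mad()
        assert (mad == 0).sum() > 0
        assert (mad.loc[truth.trend_transcript_ids] > 0).all()


class TestCaseControl:
    def _setup(self, seed, **kw):
        cfg = sd.SimConfig(seed=seed, n_transcripts=20, n_trend=1, n_snps=10, **kw)
        counts, truth = sd.gen_tissue_counts(cfg)
        n = cfg.n_cases + cfg.n_controls
        g = sd.gen_genotypes(cfg, n_individuals=n, stream="assoc")
        sd.assign_eqtls(cfg, truth, g)
        covars = sd.gen_covariates(
            n, np.random.default_rng(seed), sample_ids=list(g.sample_ids), n_pcs=10
        )
        model = truth.prediction_model(truth.trend_transcript_ids[0])
        status = sd.gen_case_control(g, model, covars, cfg)
        return cfg, g, covars, model, status

    def test_case_count_calibrated(self):
        cfg, g, covars, model, status = self._setup(seed=1)
        expected = cfg.n_cases
        assert abs(status.sum() - expected) < 4 * np.sqrt(expected)

    def test_deterministic(self):
        *_, s1 = self._setup(seed=2)
        *_, s2 = self._setup(seed=2)
        pd.testing.assert_series_equal(s1, s2)

    def test_null_or_covered(self):
        cover = 0
        reps = 20
        for seed in range(reps):
            cfg, g, covars, model, status = self._setup(
                seed=seed, true_or_per_log2=1.0, n_cases=200, n_controls=800
            )
            pred = predict_expression(g, model)
            res = associate(pred, status, covars)
            cover += res.ci_lower <= 1.0 <= res.ci_upper
        assert cover / reps >= 0.9

    def test_doubling_log_odds_doubles_estimate(self):
        def mean_beta(or_value, reps=40):
            betas = []
            for seed in range(reps):
                cfg, g, covars, model, status = self._setup(
                    seed=seed + 100, true_or_per_log2=or_value,
                    n_cases=600, n_controls=2400,
                )
                pred = predict_expression(g, model)
                res = associate(pred, status, covars)
                betas.append(np.log(res.odds_ratio))
            return np.mean(betas)

        b1 = mean_beta(1.2)
        b2 = mean_beta(1.2**2)
        assert b2 == pytest.approx(2 * b1, abs=0.08)


class TestCandidateTable:
    def _truth_geno(self, seed=0):
        cfg = sd.SimConfig(seed=seed, n_transcripts=30, n_trend=3, n_snps=100)
        _, truth = sd.gen_tissue_counts(cfg)
        g = sd.gen_genotypes(cfg)
        sd.assign_eqtls(cfg, truth, g)
        return cfg, truth, g

    def test_no_decoys_row_count(self):
        cfg, truth, g = self._truth_geno()
        table = sd.gen_candidate_table(truth, g, n_decoys=0)
        assert len(table) == sum(len(v) for v in truth.eqtl_map.values())

    def test_contains_all_true_pairs(self):
        cfg, truth, g = self._truth_geno()
        table = sd.gen_candidate_table(truth, g, n_decoys=4, seed=5)
        pairs = set(map(tuple, table.to_numpy()))
        for t, entries in truth.eqtl_map.items():
            for s, _, _ in entries:
                assert (t, s) in pairs

    def test_round_trips_through_tsv(self, tmp_path):
        cfg, truth, g = self._truth_geno()
        table = sd.gen_candidate_table(truth, g, n_decoys=2, seed=1)
        path = tmp_path / "cand.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(table, back)


class TestTruthSerialization:
    def test_truth_json_round_trip(self, tmp_path):
        cfg = sd.SimConfig(seed=1, n_transcripts=20, n_trend=2)
        _, truth = sd.gen_tissue_counts(cfg)
        g = sd.gen_genotypes(cfg)
        sd.assign_eqtls(cfg, truth, g)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = sd.SyntheticTruth.from_json(path)
        assert back.trend_transcript_ids == truth.trend_transcript_ids
        assert back.eqtl_map == truth.eqtl_map
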