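"""Filtering, imputation and normalization stages: exact rules + recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.impute import KNNImputer

from fibromark.preprocess import (
    MethylationCohort,
    PreprocessParams,
    apply_bead_filter,
    bmiq_normalize,
    correct_color_bias,
    drop_high_missing_probes,
    drop_snp_probes,
    filter_low_variance,
    impute_knn,
    mask_by_detection,
    read_cohort,
    run_preprocess,
    write_cohort,
)
from fibromark.simdata import MethCohortConfig, simulate_methylation_cohort


class TestBeadFilter:
    def test_high_bead_counts_untouched(self, tiny_cohort):
        out = apply_bead_filter(tiny_cohort, min_beads=3)
        pd.testing.assert_frame_equal(out.detection_p, tiny_cohort.detection_p)

    def test_low_bead_cell_sets_detection_p_to_one(self, tiny_cohort):
        tiny_cohort.bead_count.iloc[2, 1] = 2
        out = apply_bead_filter(tiny_cohort, min_beads=3)
        assert out.detection_p.iloc[2, 1] == 1.0
        # beta untouched at this stage
        pd.testing.assert_frame_equal(out.beta, tiny_cohort.beta)

    def test_zero_threshold_is_vacuous(self, tiny_cohort):
        tiny_cohort.bead_count.iloc[0, 0] = 0
        out = apply_bead_filter(tiny_cohort, min_beads=0)
        pd.testing.assert_frame_equal(out.detection_p, tiny_cohort.detection_p)

    def test_refuses_missing_bead_layer(self, tiny_cohort):
        tiny_cohort.bead_count = None
        with pytest.raises(ValueError, match="bead"):
            apply_bead_filter(tiny_cohort)


class TestDetectionMask:
    def test_no_masking_when_all_pass(self, tiny_cohort):
        out, n = mask_by_detection(tiny_cohort, 0.01)
        assert n == 0 and not out.beta.isna().any().any()

    def test_cell_above_threshold_masked(self, tiny_cohort):
        tiny_cohort.detection_p.iloc[1, 2] = 0.02
        out, n = mask_by_detection(tiny_cohort, 0.01)
        assert n == 1 and np.isnan(out.beta.iloc[1, 2])

    def test_threshold_is_strict(self, tiny_cohort):
        tiny_cohort.detection_p.iloc[1, 2] = 0.01
        out, n = mask_by_detection(tiny_cohort, 0.01)
        assert n == 0 and not np.isnan(out.beta.iloc[1, 2])


class TestMissingnessFilter:
    def test_proportions_around_cutoff(self):
        probes = pd.Index([f"cg{i:08d}" for i in range(2)], name="probe_id")
        samples = pd.Index([f"S{i}" for i in range(24)], name="sample_id")
        beta = pd.DataFrame(0.5, index=probes, columns=samples)
        beta.iloc[0, :8] = np.nan  # 8/24 = 0.333 > 0.3 -> dropped
        beta.iloc[1, :7] = np.nan  # 7/24 = 0.292 -> kept
        annotation = pd.DataFrame(
            {"design_type": "I", "snp_associated": False}, index=probes
        )
        sheet = pd.DataFrame(
            {"fibrosis": 0, "age": 50.0, "smoker_ever": 0, "chemotherapy": 0},
            index=samples,
        )
        cohort = MethylationCohort(beta=beta, annotation=annotation, samples=sheet)
        out, dropped = drop_high_missing_probes(cohort, 0.3)
        assert dropped == ["cg00000000"]
        assert list(out.beta.index) == ["cg00000001"]

    def test_complete_matrix_untouched(self, tiny_cohort):
        out, dropped = drop_high_missing_probes(tiny_cohort, 0.3)
        assert dropped == [] and out.n_probes == tiny_cohort.n_probes


class TestSnpFilter:
    def test_flagged_probes_removed(self, tiny_cohort):
        out, dropped = drop_snp_probes(tiny_cohort)
        assert dropped == ["cg00000002"]
        assert out.n_probes == 5

    def test_no_flags_is_identity(self, tiny_cohort):
        tiny_cohort.annotation["snp_associated"] = False
        out, dropped = drop_snp_probes(tiny_cohort)
        assert dropped == [] and out.n_probes == tiny_cohort.n_probes

    def test_all_flagged_warns_and_empties(self, tiny_cohort):
        tiny_cohort.annotation["snp_associated"] = True
        with pytest.warns(UserWarning, match="empty"):
            out, _ = drop_snp_probes(tiny_cohort)
        assert out.n_probes == 0

    def test_refuses_missing_flag(self, tiny_cohort):
        tiny_cohort.annotation = tiny_cohort.annotation.drop(columns=["snp_associated"])
        with pytest.raises(ValueError, match="snp_associated"):
            drop_snp_probes(tiny_cohort)


class TestKnnImputation:
    def test_complete_matrix_unchanged(self):
        beta = pd.DataFrame(np.random.default_rng(0).random((30, 5)))
        pd.testing.assert_frame_equal(impute_knn(beta, k=5), beta)

    def test_degenerate_neighborhood_recovers_shared_value(self):
        # 11 near-identical probes; the masked cell must equal the value the
        # neighbours share at that sample
        base = np.tile(np.linspace(0.2, 0.8, 6), (11, 1))
        base += np.random.default_rng(1).normal(0, 1e-4, base.shape)
        beta = pd.DataFrame(base)
        truth = beta.iloc[0, 3]
        beta.iloc[0, 3] = np.nan
        out = impute_knn(beta, k=10)
        assert out.iloc[0, 3] == pytest.approx(truth, abs=1e-3)

    def test_matches_reference_knn_imputer(self):
        rng = np.random.default_rng(2)
        X = rng.random((150, 10))
        X[rng.random(X.shape) < 0.05] = np.nan
        ours = impute_knn(pd.DataFrame(X), k=10).to_numpy()
        ref = KNNImputer(n_neighbors=10, weights="distance").fit_transform(X)
        assert np.abs(ours - ref).max() < 1e-12

    def test_mask_and_recover_beats_global_mean(self):
        # correlated probes (shared per-sample factors): recovery error is
        # below the probe-wise spread and below global-mean imputation
        rng = np.random.default_rng(3)
        n_probes, n_samples = 800, 24
        factor = rng.normal(0, 1, n_samples)
        base = rng.uniform(0.2, 0.8, n_probes)
        load = rng.uniform(0.05, 0.15, n_probes) * rng.choice([-1, 1], n_probes)
        full = np.clip(
            base[:, None] + load[:, None] * factor[None, :]
            + rng.normal(0, 0.02, (n_probes, n_samples)),
            0.01, 0.99,
        )
        mask = rng.random(full.shape) < 0.01
        holey = full.copy()
        holey[mask] = np.nan
        rec = impute_knn(pd.DataFrame(holey), k=10).to_numpy()
        rmse = np.sqrt(np.mean((rec[mask] - full[mask]) ** 2))
        global_rmse = np.sqrt(np.mean((full.mean() - full[mask]) ** 2))
        probe_sd = full.std(axis=1).mean()
        assert rmse < probe_sd
        assert rmse < global_rmse

    def test_small_matrix_uses_available_neighbours(self):
        beta = pd.DataFrame(np.random.default_rng(4).random((5, 4)))
        beta.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="neighbours"):
            out = impute_knn(beta, k=10)
        assert not out.isna().any().any()


class TestColorCorrection:
    @staticmethod
    def _channel_pools(cohort):
        ch = cohort.channel.to_numpy()
        M = cohort.signal_meth.to_numpy()
        U = cohort.signal_unmeth.to_numpy()
        red = np.concatenate([M[ch == "red"].ravel(), U[ch == "red"].ravel(),
                              U[ch == "both"].ravel()])
        green = np.concatenate([M[ch == "green"].ravel(), U[ch == "green"].ravel(),
                                M[ch == "both"].ravel()])
        return red, green

    def test_identical_channels_are_a_fixed_point(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(1000, 8000, 20)
        u = rng.uniform(1000, 8000, 20)
        M = np.concatenate([m, m])[:, None]
        U = np.concatenate([u, u])[:, None]
        probes = pd.Index([f"cg{i:08d}" for i in range(40)], name="probe_id")
        samples = pd.Index(["S0"], name="sample_id")
        beta = pd.DataFrame(M / (M + U + 100), index=probes, columns=samples)
        cohort = MethylationCohort(
            beta=beta,
            annotation=pd.DataFrame({"design_type": "I", "snp_associated": False},
                                    index=probes),
            samples=pd.DataFrame(
                {"fibrosis": 0, "age": 50.0, "smoker_ever": 0, "chemotherapy": 0},
                index=samples,
            ),
            signal_meth=pd.DataFrame(M, index=probes, columns=samples),
            signal_unmeth=pd.DataFrame(U, index=probes, columns=samples),
            channel=pd.Series(["red"] * 20 + ["green"] * 20, index=probes),
        )
        out = correct_color_bias(cohort)
        assert np.abs(out.beta.to_numpy() - beta.to_numpy()).max() < 1e-6

    def test_dye_bias_ks_reduced(self):
        cfg = MethCohortConfig(
            seed=3, n_probes=3000, n_loci=600, dye_bias=0.5,
            detection_fail_rate=0.0, low_bead_rate=0.0, type2_compression=1.0,
        )
        cohort, _ = simulate_methylation_cohort(cfg)
        out = correct_color_bias(cohort)
        red0, green0 = self._channel_pools(cohort)
        red1, green1 = self._channel_pools(out)
        pre = stats.ks_2samp(red0[:15000], green0[:15000]).statistic
        post = stats.ks_2samp(red1[:15000], green1[:15000]).statistic
        assert post < 0.2 * pre

    def test_within_channel_order_preserved(self):
        cfg = MethCohortConfig(seed=4, n_probes=500, n_loci=100, dye_bias=0.3)
        cohort, _ = simulate_methylation_cohort(cfg)
        out = correct_color_bias(cohort)
        ch = cohort.channel.to_numpy()
        for lab in ("red", "green"):
            pre = cohort.signal_meth.to_numpy()[ch == lab, 0]
            post = out.signal_meth.to_numpy()[ch == lab, 0]
            assert (np.argsort(pre) == np.argsort(post)).all()

    def test_skips_without_channel_info(self, tiny_cohort):
        with pytest.warns(UserWarning, match="skipped"):
            out = correct_color_bias(tiny_cohort)
        pd.testing.assert_frame_equal(out.beta, tiny_cohort.beta)


class TestBmiq:
    def test_type1_probes_bit_identical(self):
        cfg = MethCohortConfig(seed=6, n_probes=2000, n_loci=400,
                               type2_compression=0.7, dye_bias=0.0)
        cohort, _ = simulate_methylation_cohort(cfg)
        design = cohort.annotation["design_type"]
        out = bmiq_normalize(cohort.beta, design)
        is1 = (design == "I").to_numpy()
        assert (out.to_numpy()[is1] == cohort.beta.to_numpy()[is1]).all()

    def test_compression_ks_strictly_reduced(self):
        cfg = MethCohortConfig(seed=7, n_probes=2000, n_loci=400,
                               type2_compression=0.7, dye_bias=0.0,
                               detection_fail_rate=0.0, low_bead_rate=0.0)
        cohort, _ = simulate_methylation_cohort(cfg)
        design = cohort.annotation["design_type"]
        out = bmiq_normalize(cohort.beta, design)
        is1 = (design == "I").to_numpy()
        is2 = (design == "II").to_numpy()
        for j in range(cohort.n_samples):
            pre = stats.ks_2samp(cohort.beta.to_numpy()[is2, j],
                                 cohort.beta.to_numpy()[is1, j]).statistic
            post = stats.ks_2samp(out.to_numpy()[is2, j],
                                  out.to_numpy()[is1, j]).statistic
            assert post < pre

    def test_monotone_within_sample(self):
        cfg = MethCohortConfig(seed=8, n_probes=1000, n_loci=200,
                               type2_compression=0.8)
        cohort, _ = simulate_methylation_cohort(cfg)
        design = cohort.annotation["design_type"]
        out = bmiq_normalize(cohort.beta, design)
        is2 = (design == "II").to_numpy()
        pre = cohort.beta.to_numpy()[is2, 0]
        post = out.to_numpy()[is2, 0]
        order = np.argsort(pre)
        assert (np.diff(post[order]) >= -1e-12).all()

    def test_constant_type2_is_defined(self):
        rng = np.random.default_rng(9)
        n1, n2 = 200, 200
        beta = pd.DataFrame(
            np.concatenate([rng.beta(2, 2, (n1, 3)), np.full((n2, 3), 0.5)])
        )
        design = pd.Series(["I"] * n1 + ["II"] * n2, index=beta.index)
        out = bmiq_normalize(beta, design)
        vals = out.to_numpy()[n1:, 0]
        assert np.isfinite(vals).all() and np.ptp(vals) < 1e-12

    def test_skips_sparse_design_type(self):
        beta = pd.DataFrame(np.random.default_rng(10).random((60, 2)))
        design = pd.Series(["I"] * 55 + ["II"] * 5, index=beta.index)
        with pytest.warns(UserWarning, match="skipped"):
            out = bmiq_normalize(beta, design)
        pd.testing.assert_frame_equal(out, beta)


class TestVarianceFilter:
    def test_constant_probe_removed(self):
        beta = pd.DataFrame([[0.5] * 4, [0.2, 0.8, 0.2, 0.8]],
                            index=["flat", "var"])
        out, dropped = filter_low_variance(beta, 0.05)
        assert dropped == ["flat"]
        assert list(out.index) == ["var"]  # sd ~ 0.35 >= 0.05

    def test_zero_threshold_is_identity(self):
        beta = pd.DataFrame([[0.5] * 4, [0.2, 0.8, 0.2, 0.8]])
        out, dropped = filter_low_variance(beta, 0.0)
        assert dropped == [] and out.shape == beta.shape


class TestRunPreprocess:
    def test_clean_simulation_only_variance_filter_drops(self):
        cfg = MethCohortConfig(
            seed=12, n_probes=1500, n_loci=300,
            detection_fail_rate=0.0, low_bead_rate=0.0,
            snp_probe_fraction=0.0, dye_bias=0.0,
        )
        cohort, _ = simulate_methylation_cohort(cfg)
        clean, report = run_preprocess(cohort)
        assert report["probes_dropped_missing"] == 0
        assert report["probes_dropped_snp"] == 0
        assert report["cells_imputed"] == 0
        assert report["probes_dropped_low_variance"] == report["probes_removed_total"]

    def test_idempotent_on_own_output(self):
        cfg = MethCohortConfig(seed=13, n_probes=1200, n_loci=240)
        cohort, _ = simulate_methylation_cohort(cfg)
        clean, _ = run_preprocess(cohort)
        clean2, report2 = run_preprocess(clean)
        assert report2["probes_removed_total"] == 0
        change = np.abs(
            clean2.beta.to_numpy() - clean.beta.loc[clean2.beta.index].to_numpy()
        ).max()
        assert change < 1e-6

    def test_stage_counts_conserve_probes(self):
        cfg = MethCohortConfig(seed=14, n_probes=1500, n_loci=300)
        cohort, _ = simulate_methylation_cohort(cfg)
        _, report = run_preprocess(cohort)
        total = (
            report["probes_dropped_missing"]
            + report["probes_dropped_snp"]
            + report["probes_dropped_low_variance"]
        )
        assert total == report["probes_in"] - report["probes_out"]

    def test_output_complete_in_unit_interval_and_deterministic(self):
        cfg = MethCohortConfig(seed=15, n_probes=1000, n_loci=200)
        cohort, _ = simulate_methylation_cohort(cfg)
        c1, _ = run_preprocess(cohort)
        c2, _ = run_preprocess(cohort)
        assert not c1.beta.isna().any().any()
        assert ((c1.beta >= 0) & (c1.beta <= 1)).all().all()
        pd.testing.assert_frame_equal(c1.beta, c2.beta)

    def test_sample_order_preserved(self):
        cfg = MethCohortConfig(seed=16, n_probes=800, n_loci=160)
        cohort, _ = simulate_methylation_cohort(cfg)
        clean, _ = run_preprocess(cohort)
        assert list(clean.beta.columns) == list(cohort.beta.columns)


class TestIO:
    def test_roundtrip(self, tiny_cohort, tmp_path):
        write_cohort(tiny_cohort, tmp_path)
        back = read_cohort(tmp_path)
        pd.testing.assert_frame_equal(back.beta, tiny_cohort.beta)
        pd.testing.assert_frame_equal(back.samples, tiny_cohort.samples,
                                      check_dtype=False)
        assert back.detection_p is not None and back.bead_count is not None

    def test_params_validation(self):
        with pytest.raises(ValueError):
            PreprocessParams(detection_p_max=1.5)
        with pytest.raises(ValueError):
            PreprocessParams(knn_k=0)
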