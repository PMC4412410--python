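"""Waveform reconstruction, error metrics, and cross-validation."""

import numpy as np
import pytest

from motorpls import (
    DegenerateDataError,
    GeneratorConfig,
    InputError,
    cross_validate,
    decile_partition,
    decile_rmse,
    encoding_model,
    error_metrics,
    error_ratio,
    generate_ensemble,
    mean_torque_reconstruction,
    predict_scores,
    reconstruct,
    simpls,
)


@pytest.fixture(scope="module")
def noiseless_rank2():
    cfg = GeneratorConfig(n_cycles=120, noise_sd=0.0)
    return generate_ensemble(cfg, seed=7)


class TestReconstruct:
    def test_zero_scores_give_sta_rows(self, default_cycles):
        ens, sig, _ = default_cycles
        pls = simpls(ens.M, sig.U, 2)
        rec = reconstruct(ens, pls, scores=np.zeros((ens.n_cycles, 2)), n_features=2)
        assert np.allclose(rec.rows, np.tile(ens.sta, (ens.n_cycles, 1)))

    def test_zero_features_equals_sta_only(self, default_cycles):
        ens, sig, _ = default_cycles
        pls = simpls(ens.M, sig.U, 2)
        rec = reconstruct(ens, pls, n_features=0)
        assert rec.source == "sta-only"
        assert np.allclose(rec.rows - ens.sta, 0.0)

    def test_noiseless_rank2_reconstructed_exactly(self, noiseless_rank2):
        ens, sig, truth = noiseless_rank2
        pls = simpls(ens.M, sig.U, 2)
        rec = reconstruct(ens, pls, n_features=2)
        scale = np.abs(ens.raw_rows()).max()
        assert np.abs(rec.rows - ens.raw_rows()).max() / scale < 1e-8

    def test_full_component_set_reproduces_ensemble(self, rng):
        rows = rng.normal(size=(20, 10))
        from motorpls import WaveformEnsemble, MotorSignals

        ens = WaveformEnsemble.from_rows(rows, sample_rate=1000.0)
        sig = MotorSignals.from_raw(rng.normal(size=(20, 2)), ("left", "right"))
        pls = simpls(ens.M, sig.U, 10)
        rec = reconstruct(ens, pls, n_features=pls.n_components)
        # measured-score reconstruction with every component restores the
        # projection of M onto the score space; with n_comp = b it is exact
        proj = pls.K @ (pls.K.T @ ens.M)
        expected = ens.sta + ens.s * proj
        assert np.allclose(rec.rows, expected, atol=1e-8)

    def test_misaligned_scores_raise(self, default_cycles):
        ens, sig, _ = default_cycles
        pls = simpls(ens.M, sig.U, 2)
        with pytest.raises(InputError):
            reconstruct(ens, pls, scores=np.zeros((10, 2)), n_features=2)
        with pytest.raises(InputError):
            reconstruct(ens, pls, n_features=5)


class TestPredictScores:
    def test_exact_linear_scores_predicted_exactly(self, noiseless_rank2):
        ens, sig, truth = noiseless_rank2
        pls = simpls(ens.M, sig.U, 2)
        k_hat = predict_scores(sig, encoding_model("independence"), pls)
        assert np.abs(k_hat - pls.K[:, :2]).max() < 1e-10

    def test_wrong_synergy_model_predicts_worse(self, noiseless_rank2):
        ens, sig, truth = noiseless_rank2
        pls = simpls(ens.M, sig.U, 2)
        k_ind = predict_scores(sig, encoding_model("independence"), pls)
        k_dt = predict_scores(sig, encoding_model("synergy_dt"), pls)
        mse_ind = np.mean((k_ind - pls.K[:, :2]) ** 2)
        mse_dt = np.mean((k_dt - pls.K[:, :2]) ** 2)
        assert mse_dt > mse_ind * 10

    def test_permuted_signals_predict_nothing(self):
        ens, sig, _ = generate_ensemble(GeneratorConfig(n_cycles=500), seed=11)
        pls = simpls(ens.M, sig.U, 2)
        rng = np.random.default_rng(0)
        shuffled = sig.take(rng.permutation(sig.n_cycles))
        k_hat = predict_scores(shuffled, encoding_model("independence"), pls)
        r = np.corrcoef(k_hat[:, 0], pls.K[:, 0])[0, 1]
        assert abs(r) < 0.1


class TestMeanTorqueReconstruction:
    def test_row_means_equal_predictions_under_perfect_fit(self, noiseless_rank2):
        ens, sig, _ = noiseless_rank2
        rec = mean_torque_reconstruction(ens, sig, encoding_model("independence"))
        # row means equal the fitted mean-torque predictions exactly
        X = encoding_model("independence").design_matrix(sig)
        Xa = np.column_stack([np.ones(ens.n_cycles), X])
        beta, *_ = np.linalg.lstsq(Xa, ens.mean_torque, rcond=None)
        assert np.allclose(rec.rows.mean(axis=1), Xa @ beta, atol=1e-10)

    def test_constant_prediction_reduces_to_shifted_sta(self, default_cycles):
        ens, sig, _ = default_cycles
        rec = mean_torque_reconstruction(ens, sig, encoding_model("independence"))
        # every row is the mean-removed STA plus that row's offset
        detrended = rec.rows - rec.rows.mean(axis=1, keepdims=True)
        assert np.allclose(detrended, ens.sta - ens.sta.mean(), atol=1e-10)

    def test_shape_error_exceeds_two_feature_model(self, default_cycles):
        ens, sig, _ = default_cycles
        pls = simpls(ens.M, sig.U, 2)
        part = decile_partition(ens)
        rec_mt = mean_torque_reconstruction(ens, sig, encoding_model("independence"))
        rec_2f = reconstruct(ens, pls, n_features=2)
        rmse_mt = decile_rmse(ens, rec_mt.rows, part)
        rmse_2f = decile_rmse(ens, rec_2f.rows, part)
        assert rmse_mt.mean() > rmse_2f.mean()


class TestErrorMetrics:
    def test_perfect_reconstruction_is_zero_error(self, rng):
        x = rng.normal(size=(4, 30))
        m = error_metrics(x, x)
        assert m.nrmse == 0.0 and m.residual_variance == pytest.approx(0.0, abs=1e-12)

    def test_zero_reconstruction_has_unit_nrmse(self, rng):
        x = rng.normal(size=100)
        assert error_metrics(x, np.zeros(100)).nrmse == pytest.approx(1.0)

    def test_offset_sensitivity_contrast(self, rng):
        # nRMSE penalises a pure offset while residual variance forgives it
        x = rng.normal(size=200)
        m = error_metrics(x, x + 0.5)
        assert m.nrmse > 0
        assert m.residual_variance == pytest.approx(0.0, abs=1e-12)

    def test_zero_rms_measured_raises(self):
        with pytest.raises(DegenerateDataError):
            error_metrics(np.zeros(10), np.ones(10))

    def test_error_ratio_identities(self):
        base = np.array([0.2, 0.4])
        assert error_ratio(base, base) == 1.0
        assert error_ratio(2 * base, base) == 2.0
        assert error_ratio(np.array([1.0, 1.5]), np.array([1.0, 1.0])) == 1.25
        with pytest.raises(DegenerateDataError):
            error_ratio(base, np.array([0.0, 1.0]))


class TestFeatureCountMonotonicity:
    def test_nrmse_flattens_after_generative_rank(self, default_cycles):
        ens, sig, _ = default_cycles
        pls = simpls(ens.M, sig.U, 4)
        raw = ens.raw_rows()
        nrmse = []
        for nf in range(5):
            rec = reconstruct(ens, pls, n_features=nf)
            nrmse.append(error_metrics(raw, rec.rows).nrmse)
        assert nrmse[1] < nrmse[0]
        assert nrmse[2] < nrmse[1]
        # monotone: measured-score reconstruction is a projection
        assert np.all(np.diff(nrmse) <= 1e-12)
        # but the gain beyond the generative rank 2 is marginal compared to
        # the gain up to it (noise features only absorb per-row noise)
        assert (nrmse[2] - nrmse[4]) < 0.15 * (nrmse[0] - nrmse[2])


class TestCrossValidate:
    def test_noiseless_independence_ratio_near_unity(self, noiseless_rank2):
        # without noise there is no generalization gap: held-out errors of
        # the independence decoder and the two-feature projection both
        # vanish and the error ratio is exactly one
        ens, sig, _ = noiseless_rank2
        cv = cross_validate(
            ens, sig, [encoding_model("independence")],
            n_reps=20, seed=0, include_mean_torque=False,
        )
        ratios = cv.ratios["independence"]
        assert np.all(np.abs(ratios - 1.0) < 0.01)
        assert np.all(cv.nrmse_2f < 1e-9)

    def test_model_ordering_under_independent_generation(self):
        ens, sig, _ = generate_ensemble(GeneratorConfig(n_cycles=400), seed=21)
        cv = cross_validate(ens, sig, n_reps=30, seed=1)
        means = {k: v.mean() for k, v in cv.ratios.items()}
        assert means["independence"] < means["synergy_dt"]
        assert means["independence"] < means["synergy_pca"]

    def test_small_decile_raises(self):
        ens, sig, _ = generate_ensemble(GeneratorConfig(n_cycles=30), seed=2)
        with pytest.raises(InputError, match="decile"):
            cross_validate(ens, sig, n_reps=2, seed=0)

    def test_single_cycle_error_exceeds_decile_average(self, default_cycles):
        ens, sig, _ = default_cycles
        pls = simpls(ens.M, sig.U, 2)
        part = decile_partition(ens)
        k_hat = predict_scores(sig, encoding_model("independence"), pls)
        rec = reconstruct(ens, pls, scores=k_hat, n_features=2)
        by_decile = decile_rmse(ens, rec.rows, part, mode="decile_mean")
        by_cycle = decile_rmse(ens, rec.rows, part, mode="per_cycle")
        assert by_cycle.mean() > by_decile.mean()
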