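"""Torque-waveform reconstruction and its error accounting.

A wingstroke's torque waveform is approximated as the ensemble mean (the
spike-triggered average, STA) plus the extracted motor features weighted by
their scores,

    M' = STA + s * K P^T,

where ``s`` undoes the overall scaling applied when the ensemble was built.
Scores can be the measured ones (projections of the recorded torque) or
predicted from an encoding model's design matrix, which turns the
decomposition into a decoder: spike timings -> feature scores -> torque.

Error is reported two ways, with deliberately different sensitivities:
normalised RMS error (residual RMS over measured RMS; sensitive to offsets)
and residual variance 1 - r^2 (insensitive to offsets, sensitive to phase
shifts). Model performance across turning deciles is summarised by the
error ratio -- the mean over deciles of each model's decile RMSE divided by
that of the two-feature reconstruction, the best rank-2 reconstruction
available. Repeated 70/30 splits stratified by decile give the
cross-validated distribution of error ratios per model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ensemble import (
    DecilePartition,
    MotorSignals,
    WaveformEnsemble,
    decile_partition,
)
from .exceptions import DegenerateDataError, InputError
from .models import EncodingModel, encoding_model
from .pls import PLSModel, simpls

__all__ = [
    "Reconstruction",
    "ErrorMetrics",
    "CrossValidationResult",
    "reconstruct",
    "predict_scores",
    "mean_torque_reconstruction",
    "error_metrics",
    "error_ratio",
    "decile_rmse",
    "cross_validate",
]


@dataclass(frozen=True)
class Reconstruction:
    """Reconstructed waveform matrix and its provenance."""

    rows: np.ndarray  # N x b reconstructed torque
    source: str  # measured-scores | model-predicted-scores | mean-torque-offset | sta-only
    n_features: int
    model_name: str | None = None


@dataclass(frozen=True)
class ErrorMetrics:
    nrmse: float
    residual_variance: float


def reconstruct(
    ensemble: WaveformEnsemble,
    pls: PLSModel,
    scores: np.ndarray | None = None,
    n_features: int = 2,
    source: str | None = None,
    model_name: str | None = None,
) -> Reconstruction:
    """Rebuild waveforms as STA + s * (scores) (features)^T.

    With ``scores=None`` the measured scores of the fitted decomposition are
    used; ``n_features=0`` returns the STA in every row.
    """
    if n_features < 0 or n_features > pls.n_components:
        raise InputError(
            f"n_features must be in [0, {pls.n_components}], got {n_features}"
        )
    K = pls.K if scores is None else np.atleast_2d(np.asarray(scores, dtype=float))
    if scores is not None and K.shape[1] < n_features:
        raise InputError("scores have fewer columns than n_features")
    n = K.shape[0] if n_features > 0 else ensemble.n_cycles
    if n_features == 0:
        rows = np.tile(ensemble.sta, (n, 1))
        return Reconstruction(rows=rows, source=source or "sta-only", n_features=0)
    if K.shape[0] != ensemble.n_cycles:
        raise InputError("scores are not row-aligned with the ensemble")
    rows = ensemble.sta + ensemble.s * (K[:, :n_features] @ pls.P[:, :n_features].T)
    default = "measured-scores" if scores is None else "model-predicted-scores"
    return Reconstruction(
        rows=rows,
        source=source or default,
        n_features=n_features,
        model_name=model_name,
    )


def predict_scores(
    signals: MotorSignals,
    model: EncodingModel,
    pls: PLSModel,
    n_features: int = 2,
    train_rows: np.ndarray | None = None,
    scores: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares prediction of each retained score from a design matrix.

    The regression (with intercept) is fitted on ``train_rows`` only when
    given -- predictions are still returned for every row, standardising the
    design with the training-row statistics -- so the function can sit
    inside a cross-validation split without leaking held-out data.
    """
    K = pls.K[:, :n_features] if scores is None else np.asarray(scores)[:, :n_features]
    X = model.design(signals, stats_rows=train_rows)
    Xa = np.column_stack([np.ones(X.shape[0]), X])
    fit_rows = np.arange(Xa.shape[0]) if train_rows is None else np.asarray(train_rows)
    if np.linalg.matrix_rank(Xa[fit_rows]) < Xa.shape[1]:
        from .models import _check_rank

        _check_rank(Xa[fit_rows])
    beta, _, _, _ = np.linalg.lstsq(Xa[fit_rows], K[fit_rows], rcond=None)
    return Xa @ beta


def mean_torque_reconstruction(
    ensemble: WaveformEnsemble,
    signals: MotorSignals,
    model: EncodingModel,
    train_rows: np.ndarray | None = None,
) -> Reconstruction:
    """STA shifted so each row's mean equals the model-predicted mean torque.

    The predicted per-cycle mean torque is added as a constant offset to the
    mean-removed STA, i.e. only wingstroke-to-wingstroke changes are taken
    to be encoded in the motor signals.
    """
    X = model.design(signals, stats_rows=train_rows)
    Xa = np.column_stack([np.ones(X.shape[0]), X])
    fit_rows = np.arange(Xa.shape[0]) if train_rows is None else np.asarray(train_rows)
    beta, _, _, _ = np.linalg.lstsq(Xa[fit_rows], ensemble.mean_torque[fit_rows], rcond=None)
    pred = Xa @ beta
    rows = (ensemble.sta - ensemble.sta.mean())[None, :] + pred[:, None]
    return Reconstruction(
        rows=rows, source="mean-torque-offset", n_features=0, model_name=model.name
    )


def error_metrics(measured: np.ndarray, reconstructed: np.ndarray) -> ErrorMetrics:
    """nRMSE and residual variance (1 - r^2) of a reconstruction.

    Both arrays are flattened; they must have equal shapes. A zero-RMS
    measured input leaves the normalisation undefined and raises.
    """
    m = np.asarray(measured, dtype=float).ravel()
    r = np.asarray(reconstructed, dtype=float).ravel()
    if m.shape != r.shape:
        raise InputError("measured and reconstructed must have equal shapes")
    rms = np.sqrt(np.mean(m**2))
    if rms == 0:
        raise DegenerateDataError("zero-RMS measured waveform: nRMSE undefined")
    nrmse = float(np.sqrt(np.mean((m - r) ** 2)) / rms)
    if np.std(r) == 0 or np.std(m) == 0:
        resid_var = 1.0  # no covariation to credit
    else:
        corr = np.corrcoef(m, r)[0, 1]
        resid_var = float(1.0 - corr**2)
    return ErrorMetrics(nrmse=nrmse, residual_variance=resid_var)


def error_ratio(model_rmse: np.ndarray, two_feature_rmse: np.ndarray) -> float:
    """Mean over deciles of RMSE_model / RMSE_2F."""
    a = np.asarray(model_rmse, dtype=float)
    b = np.asarray(two_feature_rmse, dtype=float)
    if a.shape != b.shape:
        raise InputError("decile RMSE vectors must be aligned")
    if np.any(b <= 0):
        raise DegenerateDataError("two-feature RMSE contains zeros: ratio undefined")
    return float(np.mean(a / b))


def decile_rmse(
    ensemble: WaveformEnsemble,
    recon_rows: np.ndarray,
    partition: DecilePartition,
    mode: str = "decile_mean",
    rows_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-decile nRMSE of a reconstruction.

    ``decile_mean`` (primary) compares the decile-average measured waveform
    with the decile-average reconstruction; ``per_cycle`` averages each
    cycle's own nRMSE within the decile.
    """
    if mode not in ("decile_mean", "per_cycle"):
        raise InputError(f"unknown decile RMSE mode {mode!r}")
    measured = ensemble.raw_rows()
    subset = (
        np.arange(ensemble.n_cycles) if rows_subset is None else np.asarray(rows_subset)
    )
    out = np.full(partition.n_groups, np.nan)
    for g in range(partition.n_groups):
        rows = subset[partition.labels[subset] == g]
        if rows.size == 0:
            continue
        if mode == "decile_mean":
            m = error_metrics(measured[rows].mean(axis=0), recon_rows[rows].mean(axis=0))
            out[g] = m.nrmse
        else:
            out[g] = np.mean(
                [error_metrics(measured[i], recon_rows[i]).nrmse for i in rows]
            )
    return out


@dataclass(frozen=True)
class CrossValidationResult:
    """Held-out error-ratio distributions from repeated stratified splits."""

    ratios: dict[str, np.ndarray]  # model name -> (n_reps,) error ratios
    nrmse_2f: np.ndarray  # (n_reps,) held-out decile-mean nRMSE of the 2F recon
    train_frac: float
    n_reps: int
    seed: int | None

    def summary(self) -> dict[str, tuple[float, float]]:
        return {k: (float(v.mean()), float(v.std())) for k, v in self.ratios.items()}


def cross_validate(
    ensemble: WaveformEnsemble,
    signals: MotorSignals,
    models: Sequence[EncodingModel] | None = None,
    n_features: int = 2,
    train_frac: float = 0.7,
    n_reps: int = 1000,
    seed: int | None = None,
    n_groups: int = 10,
    include_mean_torque: bool = True,
) -> CrossValidationResult:
    """Repeated stratified 70/30 cross-validation of the reconstructions.

    Each repetition draws ``train_frac`` of every turning decile as a
    training set, refits the full decomposition (centring, scaling and
    SIMPLS) on the training rows only, fits the score regressions of every
    encoding model on those rows, and evaluates per-decile reconstruction
    RMSE on the held-out rows. The per-model error ratio (vs. the held-out
    two-feature reconstruction) is collected per repetition. Mean-torque
    variants are reported as ``"mean_torque:<model>"``.
    """
    if models is None:
        models = [encoding_model(n) for n in ("independence", "synergy_dt", "synergy_pca")]
    if ensemble.n_cycles != signals.n_cycles:
        raise InputError("ensemble and signals are not row-aligned")
    partition = decile_partition(ensemble, n_groups=n_groups)
    for g in range(n_groups):
        size = partition.rows_in_group(g).size
        if size < 4:
            raise InputError(f"decile {g} has only {size} cycles; need >= 4")
    rng = np.random.default_rng(seed)
    raw = ensemble.raw_rows()

    names = [m.name for m in models]
    if include_mean_torque:
        names += [f"mean_torque:{m.name}" for m in models]
    ratios = {name: np.empty(n_reps) for name in names}
    nrmse_2f = np.empty(n_reps)

    for rep in range(n_reps):
        train, test = [], []
        for g in range(n_groups):
            rows = partition.rows_in_group(g)
            perm = rng.permutation(rows)
            n_train = max(int(round(train_frac * rows.size)), 2)
            n_train = min(n_train, rows.size - 1)
            train.append(perm[:n_train])
            test.append(perm[n_train:])
        train = np.sort(np.concatenate(train))
        test = np.sort(np.concatenate(test))

        # refit the decomposition on the training rows only
        sta_t = raw[train].mean(axis=0)
        centered = raw[train] - sta_t
        s_t = float(np.sqrt(np.mean(centered**2)))
        U_train_stats = MotorSignals.from_raw(signals.raw[train], signals.labels)
        pls_t = simpls(centered / s_t, U_train_stats.U, n_features)

        M_test = (raw[test] - sta_t) / s_t
        k_test_meas = pls_t.project_scores(M_test)
        recon_2f_test = sta_t + s_t * (k_test_meas @ pls_t.P.T)

        def _decile_nrmse(recon_test_rows):
            out = []
            for g in range(n_groups):
                rows = test[partition.labels[test] == g]
                if rows.size == 0:
                    continue
                sel = np.isin(test, rows)
                m = error_metrics(
                    raw[rows].mean(axis=0), recon_test_rows[sel].mean(axis=0)
                )
                out.append(m.nrmse)
            return np.asarray(out)

        rmse_2f = _decile_nrmse(recon_2f_test)
        nrmse_2f[rep] = rmse_2f.mean()

        def _ratio(rmse_model):
            # on noiseless data both errors vanish: identical models, ratio 1
            both_zero = (rmse_model < 1e-9) & (rmse_2f < 1e-9)
            return float(np.where(both_zero, 1.0, rmse_model / rmse_2f).mean())

        # full-length measured scores for fitting the score regressions
        K_full = pls_t.project_scores((raw - sta_t) / s_t)
        for model in models:
            K_hat = predict_scores(
                signals, model, pls_t, n_features=n_features,
                train_rows=train, scores=K_full,
            )
            recon_rows = sta_t + s_t * (K_hat[test] @ pls_t.P.T)
            ratios[model.name][rep] = _ratio(_decile_nrmse(recon_rows))
            if include_mean_torque:
                X = model.design(signals, stats_rows=train)
                Xa = np.column_stack([np.ones(X.shape[0]), X])
                mt = raw.mean(axis=1)
                beta, _, _, _ = np.linalg.lstsq(Xa[train], mt[train], rcond=None)
                pred = Xa @ beta
                rows_mt = (sta_t - sta_t.mean())[None, :] + pred[test, None]
                ratios[f"mean_torque:{model.name}"][rep] = _ratio(_decile_nrmse(rows_mt))
    return CrossValidationResult(
        ratios=ratios, nrmse_2f=nrmse_2f, train_frac=train_frac,
        n_reps=n_reps, seed=seed,
    )
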