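"""Encoding models and their comparison by leave-one-out PRESS.

Four hypotheses about how the paired downstroke muscles encode torque are
cast as regression design matrices over the per-cycle spike timings:

* ``independence`` -- both timings (t_L, t_R) enter as separate predictors;
* ``synergy_dt``   -- only the timing difference dt = t_L - t_R (the
  physiologically motivated differential synergy);
* ``synergy_pca``  -- only the first principal component of the two
  standardised timings (the data-driven, empirical synergy);
* ``redundancy_left`` / ``redundancy_right`` -- only one muscle's timing.

Each model predicts, with an intercept, the per-cycle responses of interest
(mean torque and the torque-feature scores k_1, k_2), and is judged by the
predicted residual sum of squares (PRESS) from leave-one-out
cross-validation. Across replicate units (animals), reduced models are
compared against the independence model with paired t-tests under a Holm
correction, with Wilcoxon signed-rank tests as a robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ensemble import MotorSignals, WaveformEnsemble
from .exceptions import InputError, RankDeficiencyError
from .pls import PLSModel

__all__ = [
    "EncodingModel",
    "ModelComparison",
    "MODEL_NAMES",
    "encoding_model",
    "press_loo",
    "empirical_synergy",
    "model_press_table",
    "compare_models",
]

MODEL_NAMES = (
    "independence",
    "synergy_dt",
    "synergy_pca",
    "redundancy_left",
    "redundancy_right",
)


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std()
    if sd == 0:
        raise InputError("zero-variance predictor column")
    return (col - col.mean()) / sd


def _col(signals: MotorSignals, label: str) -> int:
    try:
        return signals.labels.index(label)
    except ValueError as exc:
        raise InputError(f"signals have no {label!r} column") from exc


def empirical_synergy(signals: MotorSignals) -> np.ndarray:
    """First principal component t_PCA of the two standardised timings.

    Projects the standardised (t_L, t_R) onto the leading eigenvector of
    their 2x2 correlation matrix, with the sign fixed so the loading on the
    right muscle's timing is positive.
    """
    jl, jr = _col(signals, "left"), _col(signals, "right")
    Z = signals.U[:, [jl, jr]]
    corr = Z.T @ Z / Z.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    w = eigvec[:, np.argmax(eigval)]
    if w[1] < 0:
        w = -w
    return Z @ w


@dataclass(frozen=True)
class EncodingModel:
    """Named mapping from motor signals to a regression design matrix."""

    name: str
    builder: Callable[[MotorSignals], np.ndarray]

    def design_matrix(self, signals: MotorSignals) -> np.ndarray:
        X = np.atleast_2d(np.asarray(self.builder(signals), dtype=float))
        if X.shape[0] == 1 and signals.n_cycles != 1:
            X = X.T
        return X

    def design(self, signals: MotorSignals, stats_rows=None) -> np.ndarray:
        """Design matrix standardised with statistics from ``stats_rows``.

        Used in train/test splits: the full-length design is built from the
        raw timings restandardised on the training rows only, so held-out
        rows see the training transform.
        """
        if stats_rows is None:
            return self.design_matrix(signals)
        stats_rows = np.asarray(stats_rows)
        ref = MotorSignals.from_raw(signals.raw[stats_rows], signals.labels)
        shifted = MotorSignals(
            U=(signals.raw - ref.center) / ref.scale,
            raw=signals.raw,
            labels=signals.labels,
            center=ref.center,
            scale=ref.scale,
            cycle_index=signals.cycle_index,
        )
        return self.design_matrix(shifted)


def _dt_column(signals: MotorSignals, on_raw: bool = True) -> np.ndarray:
    jl, jr = _col(signals, "left"), _col(signals, "right")
    if on_raw:
        return _standardize(signals.raw[:, jl] - signals.raw[:, jr])
    return _standardize(signals.U[:, jl] - signals.U[:, jr])


def encoding_model(name: str, dt_on_raw: bool = True) -> EncodingModel:
    """Construct one of the named encoding models.

    ``dt_on_raw`` selects whether the differential synergy is computed on
    raw timings (then standardised as a single column, the default) or as
    the difference of the standardised columns.
    """
    if name == "independence":
        builder = lambda s: s.U[:, [_col(s, "left"), _col(s, "right")]]
    elif name == "synergy_dt":
        builder = lambda s: _dt_column(s, on_raw=dt_on_raw)
    elif name == "synergy_pca":
        builder = empirical_synergy
    elif name == "redundancy_left":
        builder = lambda s: s.U[:, _col(s, "left")]
    elif name == "redundancy_right":
        builder = lambda s: s.U[:, _col(s, "right")]
    else:
        raise InputError(f"unknown encoding model {name!r}")
    return EncodingModel(name=name, builder=builder)


def _check_rank(Xa: np.ndarray):
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        # name the offending columns via pivoted QR (intercept is column 0)
        from scipy.linalg import qr

        _, _, piv = qr(Xa, mode="economic", pivoting=True)
        bad = sorted(int(j) - 1 for j in piv[rank:])
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear column(s) {bad}",
            columns=bad,
        )


def press_loo(
    X: np.ndarray, y: np.ndarray, add_intercept: bool = True
) -> tuple[float, np.ndarray]:
    """Leave-one-out PRESS of an OLS regression, via the hat-matrix shortcut.

    The leave-one-out residual for observation i equals e_i / (1 - h_ii)
    where e is the full-fit residual and h the leverage; this is exactly
    equal to explicit refitting of every fold. Returns ``(press, yhat_loo)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n = y.size
    Xa = np.column_stack([np.ones(n), X]) if add_intercept else X
    if n <= Xa.shape[1]:
        raise InputError(f"need N > p + 1 (N={n}, p+1={Xa.shape[1]})")
    _check_rank(Xa)
    Q, _ = np.linalg.qr(Xa)
    h = (Q**2).sum(axis=1)
    beta, _, _, _ = np.linalg.lstsq(Xa, y, rcond=None)
    e = y - Xa @ beta
    loo_resid = e / (1.0 - h)
    press = float(loo_resid @ loo_resid)
    return press, y - loo_resid


def model_press_table(
    signals: MotorSignals,
    pls: PLSModel,
    ensemble: WaveformEnsemble,
    models: Sequence[EncodingModel] | None = None,
) -> pd.DataFrame:
    """PRESS of every model for each response (mean torque, k_1, k_2)."""
    if models is None:
        models = [encoding_model(name) for name in MODEL_NAMES]
    responses = {"mean_torque": ensemble.mean_torque}
    for i in range(min(2, pls.n_components)):
        responses[f"k{i + 1}"] = pls.K[:, i]
    rows = []
    for resp_name, y in responses.items():
        for model in models:
            X = model.design_matrix(signals)
            press, _ = press_loo(X, y)
            rows.append({"response": resp_name, "model": model.name, "press": press})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ModelComparison:
    """Per-unit PRESS values and paired tests against independence."""

    table: pd.DataFrame  # unit, response, model, press
    tests: pd.DataFrame | None  # response, model, mean_diff, t, p_holm, wilcoxon_p
    alpha: float = 0.05

    def significantly_worse(self, response: str, model: str) -> bool:
        """True if ``model`` has significantly higher PRESS than independence."""
        if self.tests is None:
            raise InputError("fewer than 3 units: no inferential output")
        row = self.tests[
            (self.tests.response == response) & (self.tests.model == model)
        ].iloc[0]
        return bool(row.p_holm < self.alpha and row.mean_diff > 0)

    def equivalent_to_independence(self, response: str) -> list[str]:
        """Models not significantly worse than independence for a response."""
        sub = self.tests[self.tests.response == response]
        return [
            r.model
            for r in sub.itertuples()
            if not (r.p_holm < self.alpha and r.mean_diff > 0)
        ]


def compare_models(
    units: Sequence[tuple[MotorSignals, PLSModel, WaveformEnsemble]],
    models: Sequence[EncodingModel] | None = None,
    alpha: float = 0.05,
) -> ModelComparison:
    """Compare encoding models across replicate units (animals).

    Computes the PRESS table per unit, then for each response pairs every
    reduced model against independence across units: paired t-tests with a
    Holm correction over the models within each response, plus Wilcoxon
    signed-rank p-values as a robustness check. With fewer than 3 units only
    the descriptive table is returned (``tests=None``).
    """
    if models is None:
        models = [encoding_model(name) for name in MODEL_NAMES]
    if not any(m.name == "independence" for m in models):
        raise InputError("the independence model is required as the reference")
    frames = []
    for u, (signals, pls, ens) in enumerate(units):
        tab = model_press_table(signals, pls, ens, models)
        tab.insert(0, "unit", u)
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)

    if len(units) < 3:
        return ModelComparison(table=table, tests=None, alpha=alpha)

    rows = []
    for resp, sub in table.groupby("response", sort=False):
        wide = sub.pivot(index="unit", columns="model", values="press")
        ref = wide["independence"].to_numpy()
        pvals, recs = [], []
        for model in models:
            if model.name == "independence":
                continue
            diff = wide[model.name].to_numpy() - ref
            t, p = stats.ttest_rel(wide[model.name], ref)
            try:
                w_p = stats.wilcoxon(diff).pvalue if np.any(diff != 0) else 1.0
            except ValueError:
                w_p = np.nan
            pvals.append(p)
            recs.append(
                {
                    "response": resp,
                    "model": model.name,
                    "mean_diff": float(diff.mean()),
                    "t": float(t),
                    "p_raw": float(p),
                    "wilcoxon_p": float(w_p),
                }
            )
        _, p_holm, _, _ = multipletests(pvals, method="holm")
        for rec, ph in zip(recs, p_holm):
            rec["p_holm"] = float(ph)
            rows.append(rec)
    return ModelComparison(table=table, tests=pd.DataFrame(rows), alpha=alpha)
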