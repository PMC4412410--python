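"""Two-sided dimensionality reduction: SIMPLS, PCA comparison, significance.

The central decomposition relates the wingstroke torque matrix ``M``
(N cycles x b samples, centred and scaled) to the spike-timing matrix ``U``
(N x k, standardised) through the cross-covariance ``S0 = M.T @ U``.
Components are extracted greedily: at each step the leading singular-vector
pair (r_i, c_i) of the current deflated S gives the torque score
``k_i = M r_i / ||M r_i||``, the torque loading (the *motor feature*)
``p_i = M.T k_i``, and the signal-side loading/score ``q_i = U.T k_i``,
``d_i = U q_i``. S is then deflated by projecting out the orthonormalised
feature direction v_i (modified Gram-Schmidt against all previous v's), and
d_i is orthogonalised against all previous torque scores so each feature
beyond the first accounts only for independent signal variation.

Because the regression runs from movement to motor signals, the number of
recoverable features is limited by the dimensionality of M, not by the rank
of U (here 2) -- the property that makes the approach usable for testing
whether more than one signal dimension is encoded.

Feature significance is assessed by permutation: rows of M are shuffled
against U, the decomposition re-run, and the per-column maximum explained
variance over the extracted features forms the chance distribution whose
upper quantile (default 99.5%) is the significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, InputError

__all__ = [
    "PLSModel",
    "PCAModel",
    "VarianceExplained",
    "FeatureSignificance",
    "simpls",
    "variance_explained",
    "significance_by_resampling",
    "pca_features",
]

#: early stop when the deflated cross-covariance is numerically exhausted
EARLY_STOP_REL_NORM = 1e-10
DEFAULT_N_FEATURES = 10
DEFAULT_N_RESAMPLES = 1000
DEFAULT_QUANTILE = 0.995


@dataclass(frozen=True)
class PLSModel:
    """Fitted SIMPLS decomposition.

    Columns of the arrays are components: torque weights ``R`` (b x n),
    signal weights ``C`` (k x n), torque loadings/features ``P`` (b x n),
    signal loadings ``Q`` (k x n), unit-norm torque scores ``K`` (N x n),
    signal scores ``D`` (N x n), regression coefficients ``B`` (n x k,
    row i = k_i.T @ U), and the orthonormal deflation directions ``V``.
    """

    R: np.ndarray
    C: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    K: np.ndarray
    D: np.ndarray
    B: np.ndarray
    V: np.ndarray
    score_norms: np.ndarray  # ||M r_i|| used to unit-normalise each score
    n_components: int
    n_requested: int
    deflation: str = "projection"

    def project_scores(self, M_new: np.ndarray) -> np.ndarray:
        """Scores of new (already centred/scaled) waveform rows.

        Applies the fitted weights with the training normalisation, so
        projected scores are on the same scale as the fitted ``K``.
        """
        return np.asarray(M_new, dtype=float) @ self.R / self.score_norms

    @property
    def exhausted(self) -> bool:
        """True when extraction stopped early (no cross-covariance left)."""
        return self.n_components < self.n_requested


@dataclass(frozen=True)
class PCAModel:
    """One-sided eigendecomposition of the M covariance (for comparison)."""

    components: np.ndarray  # b x n
    scores: np.ndarray  # N x n (unit-norm columns, as for PLS)
    variance_fraction: np.ndarray  # n


@dataclass(frozen=True)
class VarianceExplained:
    """Per-feature explained variance in each U column.

    ``incremental[i, j]`` is the additional fraction of U column j's
    variance captured when feature i joins the sequential regression of
    that column on the scores k_1..k_i; ``cumulative`` is its running sum.
    """

    incremental: np.ndarray
    cumulative: np.ndarray

    def normalized(self, at: int = 10) -> "VarianceExplained":
        """Scale so the cumulative value with ``at`` features equals 1."""
        idx = min(at, self.cumulative.shape[0]) - 1
        denom = self.cumulative[idx]
        if np.any(denom <= 0):
            raise DegenerateDataError("cannot normalise: zero cumulative variance")
        return VarianceExplained(self.incremental / denom, self.cumulative / denom)


@dataclass(frozen=True)
class FeatureSignificance:
    """Permutation-test outcome for the extracted features."""

    observed: np.ndarray  # n_features x k incremental explained variance
    threshold: np.ndarray  # per U column (max-statistic) or n_features x k
    flags: np.ndarray  # boolean, observed > threshold
    null_max: np.ndarray  # n_resamples x k chance per-column maxima
    quantile: float
    n_resamples: int
    per_feature: bool
    seed: int | None

    @property
    def n_significant(self) -> np.ndarray:
        """Number of significant features per U column."""
        return self.flags.sum(axis=0)


def _leading_pair(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading left/right singular vectors of the deflated cross-covariance."""
    Ul, sv, Vt = np.linalg.svd(S, full_matrices=False)
    return Ul[:, 0], Vt[0]


def simpls(
    M: np.ndarray,
    U: np.ndarray,
    n_components: int,
    deflation: str = "projection",
) -> PLSModel:
    """SIMPLS decomposition of torque against motor signals.

    Parameters
    ----------
    M
        N x b centred (and scaled) waveform matrix.
    U
        N x k standardised signal matrix, rows aligned with M.
    n_components
        Number of features to extract (at most min(N-1, b)); extraction
        stops early if the cross-covariance is exhausted.
    deflation
        ``"projection"`` (default) removes the orthonormalised feature
        direction from S at each step; ``"residual"`` recomputes S from the
        score-residual matrices instead, which makes the residual
        reconstruction of S exact at every step.
    """
    M = np.asarray(M, dtype=float)
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if U.shape[0] != M.shape[0]:
        raise InputError("M and U must have the same number of rows (cycles)")
    if deflation not in ("projection", "residual"):
        raise InputError(f"unknown deflation scheme {deflation!r}")
    n, b = M.shape
    k = U.shape[1]
    if np.any(U.std(axis=0) == 0):
        raise DegenerateDataError("U has a zero-variance column")
    if not 1 <= n_components <= min(n - 1, b):
        raise InputError(
            f"n_components must be in [1, min(N-1, b)] = [1, {min(n - 1, b)}]"
        )

    S0 = M.T @ U
    norm_S0 = np.linalg.norm(S0)
    if norm_S0 == 0:
        raise DegenerateDataError("cross-covariance is identically zero")
    S = S0.copy()
    R = np.zeros((b, n_components))
    C = np.zeros((k, n_components))
    P = np.zeros((b, n_components))
    Q = np.zeros((k, n_components))
    K = np.zeros((n, n_components))
    D = np.zeros((n, n_components))
    B = np.zeros((n_components, k))
    V = np.zeros((b, n_components))
    norms = np.zeros(n_components)

    found = 0
    for i in range(n_components):
        if np.linalg.norm(S) / norm_S0 < EARLY_STOP_REL_NORM:
            break
        r, c = _leading_pair(S)
        ki = M @ r
        nk = np.linalg.norm(ki)
        if nk == 0:
            break
        ki = ki / nk
        p = M.T @ ki
        # sign convention: largest-magnitude element of the feature positive
        if p[np.argmax(np.abs(p))] < 0:
            r, c, ki, p = -r, -c, -ki, -p
        q = U.T @ ki
        d = U @ q
        # modified Gram-Schmidt of the deflation direction against V
        # (applied twice for numerical stability)
        v = p.copy()
        for _ in range(2):
            v = v - V[:, :i] @ (V[:, :i].T @ v)
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v = v / nv
        # U scores made orthogonal to all previous M scores
        d = d - K[:, :i] @ (K[:, :i].T @ d)

        R[:, i], C[:, i], P[:, i], Q[:, i] = r, c, p, q
        K[:, i], D[:, i], V[:, i] = ki, d, v
        B[i] = ki @ U
        norms[i] = nk
        found = i + 1

        if deflation == "projection":
            S = S - np.outer(v, v @ S)
        else:  # residual: S from the deflated M and U matrices directly
            Mres = M - K[:, :found] @ (K[:, :found].T @ M)
            Ures = U - K[:, :found] @ (K[:, :found].T @ U)
            S = Mres.T @ Ures

    if found < n_components:
        warnings.warn(
            f"cross-covariance exhausted: {found} of {n_components} components",
            stacklevel=2,
        )
    sl = slice(0, found)
    return PLSModel(
        R=R[:, sl], C=C[:, sl], P=P[:, sl], Q=Q[:, sl],
        K=K[:, sl], D=D[:, sl], B=B[sl], V=V[:, sl], score_norms=norms[sl],
        n_components=found, n_requested=n_components, deflation=deflation,
    )


def _scores_of(model_or_scores) -> np.ndarray:
    if isinstance(model_or_scores, (PLSModel, PCAModel)):
        return model_or_scores.K if isinstance(model_or_scores, PLSModel) else model_or_scores.scores
    return np.asarray(model_or_scores, dtype=float)


def variance_explained(model_or_scores, U: np.ndarray) -> VarianceExplained:
    """Sequential explained variance of each U column by the ordered scores.

    For each i, every column of U is regressed on the first i score columns
    (least squares); the incremental value of feature i is the resulting
    gain in R^2. The cumulative curve is nondecreasing by construction.
    """
    K = np.atleast_2d(_scores_of(model_or_scores))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    n, n_comp = K.shape
    ss_tot = ((U - U.mean(axis=0)) ** 2).sum(axis=0)
    if np.any(ss_tot == 0):
        raise DegenerateDataError("U has a zero-variance column")
    cumulative = np.empty((n_comp, U.shape[1]))
    for i in range(n_comp):
        X = np.column_stack([np.ones(n), K[:, : i + 1]])
        coef, _, _, _ = np.linalg.lstsq(X, U, rcond=None)
        resid = U - X @ coef
        cumulative[i] = 1.0 - (resid**2).sum(axis=0) / ss_tot
    incremental = np.diff(cumulative, axis=0, prepend=0.0)
    return VarianceExplained(incremental=incremental, cumulative=cumulative)


def significance_by_resampling(
    M: np.ndarray,
    U: np.ndarray,
    n_features: int = DEFAULT_N_FEATURES,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    quantile: float = DEFAULT_QUANTILE,
    seed: int | None = None,
    mode: str = "permute_m",
    per_feature: bool = False,
) -> FeatureSignificance:
    """Permutation significance of the extracted features.

    For each resample the rows of M are permuted against the fixed U rows
    (``mode="permute_m"``; ``"joint"`` additionally shuffles U rows
    independently), the decomposition re-run, and the per-column maximum
    single-feature explained variance recorded. The threshold is the
    requested upper quantile of these chance maxima -- a conservative,
    family-wise control over the extracted features. ``per_feature=True``
    instead thresholds each feature rank against its own chance
    distribution.
    """
    if n_resamples < 100:
        warnings.warn(
            f"n_resamples={n_resamples} < 100: quantile estimate unstable",
            stacklevel=2,
        )
    if mode not in ("permute_m", "joint"):
        raise InputError(f"unknown resampling mode {mode!r}")
    M = np.asarray(M, dtype=float)
    U = np.atleast_2d(np.asarray(U, dtype=float))
    model = simpls(M, U, n_features)
    observed = variance_explained(model, U).incremental

    rng = np.random.default_rng(seed)
    k = U.shape[1]
    null_max = np.empty((n_resamples, k))
    null_full = np.empty((n_resamples, n_features, k)) if per_feature else None
    for rep in range(n_resamples):
        Mp = M[rng.permutation(M.shape[0])]
        Up = U[rng.permutation(U.shape[0])] if mode == "joint" else U
        null_model = simpls(Mp, Up, n_features)
        inc = variance_explained(null_model, Up).incremental
        if inc.shape[0] < n_features:  # early-stopped null fit
            inc = np.vstack([inc, np.zeros((n_features - inc.shape[0], k))])
        null_max[rep] = inc.max(axis=0)
        if per_feature:
            null_full[rep] = inc

    if per_feature:
        threshold = np.quantile(null_full, quantile, axis=0)
    else:
        threshold = np.quantile(null_max, quantile, axis=0)
    flags = observed > threshold
    return FeatureSignificance(
        observed=observed,
        threshold=threshold,
        flags=flags,
        null_max=null_max,
        quantile=quantile,
        n_resamples=n_resamples,
        per_feature=per_feature,
        seed=seed,
    )


def pca_features(M: np.ndarray, n_components: int) -> PCAModel:
    """One-sided PCA of the waveform matrix (eigendecomposition of cov(M)).

    Used only for the PCA-vs-PLS comparison; scores are unit-normalised so
    the same variance-explained accounting applies against U.
    """
    M = np.asarray(M, dtype=float)
    Mc = M - M.mean(axis=0)
    Ul, sv, Vt = np.linalg.svd(Mc, full_matrices=False)
    n_components = min(n_components, sv.size)
    comps = Vt[:n_components].T
    # match the PLS sign convention
    for j in range(n_components):
        if comps[np.argmax(np.abs(comps[:, j])), j] < 0:
            comps[:, j] = -comps[:, j]
            Ul[:, j] = -Ul[:, j]
    total = (sv**2).sum()
    frac = sv[:n_components] ** 2 / total if total > 0 else np.zeros(n_components)
    return PCAModel(components=comps, scores=Ul[:, :n_components], variance_fraction=frac)
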