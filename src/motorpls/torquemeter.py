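"""Torquemeter dynamics: forward simulation, calibration, and inversion.

A tethered insect applies a yaw torque tau(t) to the shaft of an optical
torquemeter. The instrument itself behaves as a forced, damped rotational
oscillator,

    I phidd + C phid + kappa phi = tau(t),

where phi is the measured rotation angle, I the rotational inertia, C the
torsional damping coefficient and kappa the torsional stiffness. Recovering
the animal's torque from the measured angle therefore requires decoupling
these instrument dynamics: this module provides the forward model
(:func:`simulate_oscillator`), least-squares calibration of (I, C, kappa)
from calibration trials (:func:`fit_oscillator`), and the inversion of the
measured angle back into applied torque (:func:`invert_oscillator`).

Torque units are opaque to the package: calibration defines them, and no
unit conversion is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .exceptions import FitError, InputError, InvalidModelError

__all__ = [
    "OscillatorModel",
    "CalibrationTrial",
    "simulate_oscillator",
    "fit_oscillator",
    "invert_oscillator",
]

#: number of samples at each edge of an inverted record that are marked
#: invalid (central differences have no neighbours there)
EDGE_INVALID = 2


@dataclass(frozen=True)
class OscillatorModel:
    """Second-order rotational oscillator (the torquemeter).

    Parameters
    ----------
    inertia
        Rotational inertia ``I`` (> 0, arbitrary consistent units).
    damping
        Torsional damping coefficient ``C`` (>= 0).
    stiffness
        Torsional stiffness ``kappa`` (> 0).
    sample_rate
        Sampling rate of all associated time series, Hz.
    """

    inertia: float
    damping: float
    stiffness: float
    sample_rate: float = 10_000.0

    def __post_init__(self):
        if not (self.inertia > 0):
            raise InvalidModelError(f"inertia must be > 0, got {self.inertia}")
        if not (self.stiffness > 0):
            raise InvalidModelError(f"stiffness must be > 0, got {self.stiffness}")
        if self.damping < 0:
            raise InvalidModelError(f"damping must be >= 0, got {self.damping}")
        if not (self.sample_rate > 0):
            raise InvalidModelError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def natural_frequency_hz(self) -> float:
        """Undamped natural frequency sqrt(kappa/I) / 2pi."""
        return float(np.sqrt(self.stiffness / self.inertia) / (2 * np.pi))

    @property
    def damping_ratio(self) -> float:
        return float(self.damping / (2 * np.sqrt(self.stiffness * self.inertia)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "inertia": self.inertia,
                "damping": self.damping,
                "stiffness": self.stiffness,
                "sample_rate": self.sample_rate,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "OscillatorModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class CalibrationTrial:
    """One calibration recording.

    ``kind='driven'`` trials carry both the applied torque and the measured
    angle; ``kind='free_decay'`` trials carry only the angle following a
    release from a deflected position (torque is None).
    """

    angle: np.ndarray
    torque: np.ndarray | None = None
    kind: str = "driven"

    def __post_init__(self):
        object.__setattr__(self, "angle", np.asarray(self.angle, dtype=float))
        if self.torque is not None:
            object.__setattr__(self, "torque", np.asarray(self.torque, dtype=float))
            if self.torque.shape != self.angle.shape:
                raise InputError("torque and angle series must have equal length")
        if self.kind not in ("driven", "free_decay"):
            raise InputError(f"unknown trial kind {self.kind!r}")
        if self.kind == "driven" and self.torque is None:
            raise InputError("driven trials require an applied-torque series")


def simulate_oscillator(
    model: OscillatorModel,
    torque: np.ndarray,
    initial_state: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Integrate ``I phidd + C phid + kappa phi = tau(t)`` for a sampled torque.

    Parameters
    ----------
    model
        Oscillator parameters; ``torque`` must be sampled at ``model.sample_rate``.
    torque
        Applied torque series, finite values.
    initial_state
        ``(angle, angular_velocity)`` at the first sample.

    Returns
    -------
    ndarray
        Angle series phi(t), same length and rate as the input.
    """
    tau = np.asarray(torque, dtype=float)
    if tau.ndim != 1:
        raise InputError("torque must be a 1-D series")
    if not np.all(np.isfinite(tau)):
        raise InputError("torque contains NaN or infinite values")
    # state-space form: x = (phi, phid)
    A = np.array(
        [
            [0.0, 1.0],
            [-model.stiffness / model.inertia, -model.damping / model.inertia],
        ]
    )
    B = np.array([[0.0], [1.0 / model.inertia]])
    C = np.array([[1.0, 0.0]])
    D = np.array([[0.0]])
    t = np.arange(tau.size) / model.sample_rate
    _, phi, _ = signal.lsim((A, B, C, D), tau, t, X0=np.asarray(initial_state, float))
    return np.atleast_1d(phi)


def _derivatives(angle: np.ndarray, fs: float, smooth_cutoff_hz: float | None):
    """Zero-phase low-pass smoothing followed by central-difference derivatives."""
    phi = np.asarray(angle, dtype=float)
    if smooth_cutoff_hz is not None:
        if not 0 < smooth_cutoff_hz < fs / 2:
            raise InputError("smoothing cutoff must lie in (0, Nyquist)")
        sos = signal.butter(4, smooth_cutoff_hz, fs=fs, output="sos")
        phi = signal.sosfiltfilt(sos, phi)
    dt = 1.0 / fs
    phid = np.gradient(phi, dt, edge_order=2)
    phidd = np.gradient(phid, dt, edge_order=2)
    return phi, phid, phidd


def invert_oscillator(
    model: OscillatorModel,
    angle: np.ndarray,
    smooth_cutoff_hz: float | None = 200.0,
    mark_edges: bool = True,
) -> np.ndarray:
    """Recover applied torque from the measured angle.

    Computes ``tau = I phidd + C phid + kappa phi`` with second-order
    central-difference derivatives after optional zero-phase low-pass
    smoothing (default cutoff 200 Hz, i.e. ten times a 20 Hz wingstroke).

    The first and last :data:`EDGE_INVALID` samples are set to NaN when
    ``mark_edges`` is true so that downstream windowing excludes them.
    """
    phi = np.asarray(angle, dtype=float)
    if phi.ndim != 1 or phi.size < 5:
        raise InputError("angle series must be 1-D with at least 5 samples")
    if not np.all(np.isfinite(phi)):
        raise InputError("angle contains NaN or infinite values")
    phi_s, phid, phidd = _derivatives(phi, model.sample_rate, smooth_cutoff_hz)
    tau = model.inertia * phidd + model.damping * phid + model.stiffness * phi_s
    if mark_edges:
        tau[:EDGE_INVALID] = np.nan
        tau[-EDGE_INVALID:] = np.nan
    return tau


def _fit_driven(trials, fs, smooth_cutoff_hz):
    """Linear regression of tau on (phidd, phid, phi), pooled over trials.

    The first/last 0.1 s of each trial are excluded: the startup transient
    and filter edges would otherwise bias the inertia estimate.
    """
    rows, rhs = [], []
    for tr in trials:
        phi, phid, phidd = _derivatives(tr.angle, fs, smooth_cutoff_hz)
        trim = max(EDGE_INVALID, min(int(round(0.1 * fs)), phi.size // 4))
        sl = slice(trim, -trim)
        rows.append(np.column_stack([phidd[sl], phid[sl], phi[sl]]))
        rhs.append(np.asarray(tr.torque, float)[sl])
    X = np.vstack(rows)
    y = np.concatenate(rhs)
    if np.ptp(X[:, 2]) == 0:
        raise FitError("angle has zero variance: calibration is under-determined")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise FitError(
            "driven calibration is under-determined (rank "
            f"{rank} < 3); use a richer stimulus"
        )
    I, C, kappa = coef
    if I <= 0 or kappa <= 0:
        raise FitError(f"non-physical fit: I={I:.3g}, kappa={kappa:.3g}")
    return float(I), float(max(C, 0.0)), float(kappa)


def _fit_free_decay(trial, fs, inertia):
    """Damped-sinusoid fit of a free decay: frequency + log-decrement.

    A free decay determines only the ratios kappa/I and C/I; the absolute
    scale is set by the supplied ``inertia``.
    """
    phi = np.asarray(trial.angle, float)
    if np.ptp(phi) == 0:
        raise FitError("angle has zero variance: free decay is degenerate")
    t = np.arange(phi.size) / fs
    # initial guesses: dominant frequency from the spectrum, decay from the
    # analytic-signal envelope
    spec = np.abs(np.fft.rfft(phi - phi.mean()))
    freqs = np.fft.rfftfreq(phi.size, 1 / fs)
    f0 = max(freqs[np.argmax(spec[1:]) + 1], freqs[1])
    env = np.abs(signal.hilbert(phi - phi.mean()))
    core = slice(phi.size // 10, -phi.size // 10 or None)
    with np.errstate(divide="ignore"):
        log_env = np.log(np.maximum(env[core], 1e-300))
    lam0 = max(-np.polyfit(t[core], log_env, 1)[0], 1e-6)

    def damped(t, a, lam, omega, phase, offset):
        return a * np.exp(-lam * t) * np.cos(omega * t + phase) + offset

    p0 = [np.ptp(phi) / 2, lam0, 2 * np.pi * f0, 0.0, phi.mean()]
    try:
        popt, _ = optimize.curve_fit(damped, t, phi, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise FitError(f"free-decay fit did not converge: {exc}") from exc
    _, lam, omega, _, _ = popt
    omega = abs(omega)
    omega_n_sq = omega**2 + lam**2  # kappa/I
    return float(inertia), float(2 * lam * inertia), float(omega_n_sq * inertia)


def fit_oscillator(
    trials: Sequence[CalibrationTrial | tuple],
    sample_rate: float = 10_000.0,
    smooth_cutoff_hz: float | None = 200.0,
    inertia: float = 1.0,
) -> OscillatorModel:
    """Least-squares estimate of (I, C, kappa) from calibration trials.

    Driven trials (known applied torque) are pooled into a single linear
    regression of tau on (phidd, phid, phi). Free-decay trials are fitted as
    damped sinusoids (frequency and log-decrement), which determine kappa/I
    and C/I; the absolute scale is then set by ``inertia``. When both kinds
    are present the driven regression takes precedence.

    Raises
    ------
    FitError
        If the input is degenerate or under-determined.
    """
    if len(trials) == 0:
        raise FitError("at least one calibration trial is required")
    trials = [
        tr if isinstance(tr, CalibrationTrial) else CalibrationTrial(*tr)
        for tr in trials
    ]
    driven = [tr for tr in trials if tr.kind == "driven"]
    decay = [tr for tr in trials if tr.kind == "free_decay"]
    if driven:
        I, C, kappa = _fit_driven(driven, sample_rate, smooth_cutoff_hz)
    else:
        fits = np.array([_fit_free_decay(tr, sample_rate, inertia) for tr in decay])
        I, C, kappa = fits.mean(axis=0)
    return OscillatorModel(
        inertia=I, damping=C, stiffness=kappa, sample_rate=sample_rate
    )
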