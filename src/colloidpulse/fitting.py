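"""Fluorescence calibration and rate-constant estimation.

An intercalating dye (SyBr Green II type) reports total nucleic-acid
concentration with a linear response.  Because the dsDNA template is present
from the start and no RNA exists yet, the signal minimum during early
production equals the template concentration; dividing the minimum by the
known template concentration calibrates the a.U./nM slope, after which

    [RNA](t) = signal(t)/slope - template

Rate estimation then works on concentration trajectories:

* production-only experiments -> linear fit of the initial rate A,
* degradation-only experiments (pre-built linker + RNaseH) -> log-linear mu,
* full fuel-limited pulses -> bounded nonlinear least squares on the
  double-exponential closed form over (A, lam, mu).

The closed form is symmetric under lam <-> mu, so a single pulse cannot
distinguish the fuel-depletion from the degradation rate; the smaller rate is
reported as lam (in this system fuel depletion is the slow decay).  Fitting
two pulses that differ only in RNaseH jointly breaks the symmetry and
identifies k2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .kinetics import KineticParams, RnaTrajectory, closed_form_rna

__all__ = [
    "FluorescenceTrace",
    "CalibrationModel",
    "FitResult",
    "calibrate",
    "to_concentration",
    "fit_production",
    "fit_degradation",
    "fit_full_pulse",
    "fit_joint_pulses",
]

#: early window excluded from calibration/fits; the chamber-heating dip
#: transiently depresses the signal before this time
DEFAULT_T_MIN_FIT = 10.0


@dataclass
class FluorescenceTrace:
    """A raw dye-intensity time series with its experimental metadata."""

    times: np.ndarray
    signal: np.ndarray
    template_nM: float
    metadata: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.size != self.signal.size or self.times.size == 0:
            raise ValueError("times and signal must be non-empty and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear dye response: slope in a.U. per nM of nucleic acid."""

    slope: float
    t_min_fit: float = DEFAULT_T_MIN_FIT

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")


@dataclass(frozen=True)
class FitResult:
    """Estimated lumped rates, optional unlumped constants, and fit diagnostics."""

    A: float  # nM/min
    lam: float  # 1/min
    mu: float  # 1/min
    residual_norm: float
    window: Tuple[float, float]
    k1: Optional[float] = None
    k2: Optional[float] = None
    k3: Optional[float] = None
    success: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "A_nM_per_min": self.A,
            "lam_per_min": self.lam,
            "mu_per_min": self.mu,
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
            "residual_norm": self.residual_norm,
            "window": list(self.window),
            "success": self.success,
            "message": self.message,
        }


def calibrate(trace: FluorescenceTrace, t_min_fit: float = DEFAULT_T_MIN_FIT) -> CalibrationModel:
    """Derive the a.U./nM slope from the post-dip signal minimum.

    The minimum of the signal during production corresponds to the time when
    only the template contributes, so slope = min(signal)/template.  Points
    before ``t_min_fit`` are excluded because the heating dip undercuts the
    true template level.
    """
    if trace.template_nM <= 0:
        raise ValueError("template_nM must be > 0")
    mask = trace.times >= t_min_fit
    if not mask.any():
        mask = np.ones_like(trace.times, dtype=bool)
    m = float(trace.signal[mask].min())
    if m <= 0:
        raise ValueError("signal minimum must be positive for calibration")
    return CalibrationModel(slope=m / trace.template_nM, t_min_fit=t_min_fit)


def to_concentration(trace: FluorescenceTrace, calib: CalibrationModel) -> RnaTrajectory:
    """Convert a.U. to RNA concentration: signal/slope minus template, floored at 0."""
    rna = trace.signal / calib.slope - trace.template_nM
    return RnaTrajectory(times=trace.times.copy(), rna=np.maximum(rna, 0.0), ntp=None)


def fit_production(traj: RnaTrajectory, window: Tuple[float, float]) -> float:
    """Least-squares slope of rna vs t on a window (degradation-free regime)."""
    t0, t1 = window
    mask = (traj.times >= t0) & (traj.times <= t1)
    if mask.sum() < 3:
        raise ValueError("window must contain at least 3 points")
    res = linregress(traj.times[mask], traj.rna[mask])
    return float(res.slope)


def fit_degradation(traj: RnaTrajectory) -> float:
    """Log-linear decay-rate estimate for a production-free trace.

    Non-positive values (noise at the tail) are masked before taking logs.
    Returns 0 for a constant trace; estimates are clipped at 0.
    """
    mask = traj.rna > 0
    if mask.sum() < 3:
        raise ValueError("need at least 3 positive samples")
    t = traj.times[mask]
    y = np.log(traj.rna[mask])
    if np.allclose(y, y[0]):
        return 0.0
    res = linregress(t, y)
    return float(max(-res.slope, 0.0))


def _noise_floor(v: np.ndarray) -> float:
    """Weighting floor for relative residuals (multiplicative dye noise).

    Intercalator noise scales with the total signal (template + RNA), so
    least squares on relative residuals (m - v)/(floor + m) is the natural
    weighting; the floor — a few percent of the peak, standing in for the
    template baseline — keeps the weights bounded near zero concentration.
    """
    return max(float(np.max(v)) * 0.05, 1e-6)


def _pulse_model(t: np.ndarray, A: float, lam: float, mu: float, rna0: float) -> np.ndarray:
    p = KineticParams.from_lumped(A, lam, mu, rna0=rna0)
    return np.asarray(closed_form_rna(p, t))


def _initial_guesses(traj: RnaTrajectory, t_min_fit: float):
    """Heuristic multistart seeds: early slope for A, tail log-slope for the slow rate."""
    t, v = traj.times, traj.rna
    imax = int(np.argmax(v))
    t_peak = max(t[imax], t_min_fit + 1.0)
    early = (t >= t_min_fit) & (t <= t_min_fit + 0.5 * (t_peak - t_min_fit))
    if early.sum() >= 3:
        A0 = max(float(linregress(t[early], v[early]).slope), 1e-6)
    else:
        A0 = max(float(v.max()) / max(t_peak, 1.0), 1e-6)
    tail = (t > t_peak) & (v > 0)
    if tail.sum() >= 3:
        slow = max(-float(linregress(t[tail], np.log(v[tail])).slope), 1e-4)
    else:
        slow = 1.0 / max(float(t[-1]), 1.0)
    # three documented starts bracketing the fast/slow rate ratio
    return [
        (A0, slow, 3.0 * slow),
        (A0, slow / 3.0, slow),
        (2.0 * A0, slow, 10.0 * slow),
    ]


def fit_full_pulse(
    traj: RnaTrajectory,
    known: Optional[Dict[str, float]] = None,
    t_min_fit: float = DEFAULT_T_MIN_FIT,
) -> FitResult:
    """Nonlinear least squares of the closed-form pulse over (A, lam, mu).

    Bounded below by 0, multistart from data-driven seeds; by the lam<->mu
    exchange symmetry the smaller decay rate is reported as lam.  When
    ``known`` provides t7, temp, ntp0 and rnaseh, the lumped rates are divided
    out into k1, k3, k2.
    """
    mask = traj.times >= t_min_fit
    if mask.sum() < 5:
        mask = np.ones_like(traj.times, dtype=bool)
    t, v = traj.times[mask], traj.rna[mask]
    rna0 = float(traj.rna[0])
    w0 = _noise_floor(v)

    def resid(theta):
        m = _pulse_model(t, *theta, rna0=rna0)
        return (m - v) / (w0 + m)

    best = None
    for x0 in _initial_guesses(traj, t_min_fit):
        try:
            sol = least_squares(resid, x0, bounds=(0.0, np.inf), method="trf")
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("pulse fit failed from all starts")

    A, r1, r2 = best.x
    lam, mu = (r1, r2) if r1 <= r2 else (r2, r1)
    k1 = k2 = k3 = None
    if known:
        scale = known["t7"] * known["temp"]
        k1 = A / (scale * known["ntp0"])
        k3 = lam / scale
        k2 = mu / known["rnaseh"] if known.get("rnaseh") else None
    return FitResult(
        A=float(A),
        lam=float(lam),
        mu=float(mu),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        window=(float(t[0]), float(t[-1])),
        k1=k1,
        k2=k2,
        k3=k3,
        success=bool(best.success),
        message=str(best.message),
    )


def fit_joint_pulses(
    trajs: Sequence[RnaTrajectory],
    rnaseh_levels: Sequence[float],
    t_min_fit: float = DEFAULT_T_MIN_FIT,
) -> FitResult:
    """Joint fit of pulses sharing (A, lam, k2) across different RNaseH levels.

    The degradation rate of trace i is constrained to mu_i = k2 * rnaseh_i,
    which breaks the lam<->mu exchange degeneracy of the single-trace fit and
    identifies the shared degradation constant k2.
    """
    if len(trajs) != len(rnaseh_levels) or len(trajs) < 2:
        raise ValueError("need >= 2 trajectories with matching rnaseh levels")
    data = []
    for traj in trajs:
        mask = traj.times >= t_min_fit
        data.append((traj.times[mask], traj.rna[mask], float(traj.rna[0])))

    floors = [_noise_floor(v) for _, v, _ in data]

    def resid(theta):
        A, lam, k2 = theta
        parts = []
        for (t, v, rna0), rh, w0 in zip(data, rnaseh_levels, floors):
            m = _pulse_model(t, A, lam, k2 * rh, rna0)
            parts.append((m - v) / (w0 + m))
        return np.concatenate(parts)

    seeds = _initial_guesses(trajs[0], t_min_fit)
    rh0 = max(rnaseh_levels)
    best = None
    for A0, slow, fast in seeds:
        for x0 in ((A0, slow, fast / rh0), (A0, fast, slow / rh0)):
            try:
                sol = least_squares(resid, x0, bounds=(0.0, np.inf), method="trf")
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("joint pulse fit failed from all starts")
    A, lam, k2 = best.x
    return FitResult(
        A=float(A),
        lam=float(lam),
        mu=float(k2 * rnaseh_levels[0]),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        window=(float(data[0][0][0]), float(data[0][0][-1])),
        k2=float(k2),
        success=bool(best.success),
        message=str(best.message),
    )
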