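"""Differential scanning fluorimetry (thermal shift) melt-curve analysis.

A hydrophobicity-sensitive dye reports protein unfolding as a sigmoidal
rise of fluorescence with temperature.  The melting temperature Tm is
operationally defined as the half-point of the transition, obtained by
fitting a Boltzmann sigmoid with linear native and unfolded baselines:

    F(T) = (bn + mn*T) + [(bu + mu*T) - (bn + mn*T)] / (1 + exp((Tm - T)/a))

Above the fluorescence maximum the dye quenches (the model no longer
applies), so curves are truncated at their global maximum before fitting.
A smoothed-first-derivative Tm is provided as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import lmfit
from scipy import stats

from .errors import DomainError, DataError

__all__ = [
    "MeltCurve",
    "MeltFitResult",
    "truncate_quench",
    "fit_melt_sigmoid",
    "tm_by_derivative",
]


@dataclass(frozen=True)
class MeltCurve:
    """One fluorescence ramp (temperatures strictly increasing, deg C)."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        F = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "fluorescence", F)
        if T.ndim != 1 or F.shape != T.shape:
            raise DataError("temperatures and fluorescence must be 1-D, equal length")
        if len(T) < 20:
            raise DataError("melt curve needs at least 20 points")
        if np.any(np.diff(T) <= 0):
            raise DataError("temperatures must be strictly increasing")
        if T[-1] - T[0] < 20.0:
            raise DataError("melt curve must span at least 20 deg C")
        if not np.all(np.isfinite(F)):
            raise DataError("fluorescence contains non-finite values")

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass
class MeltFitResult:
    tm: float                    # deg C (nan when no transition)
    width: float                 # a, deg C
    baseline_native: tuple       # (intercept, slope)
    baseline_unfolded: tuple     # (intercept, slope)
    method: str                  # "sigmoid" | "derivative"
    residual_rms: float
    converged: bool
    message: str = ""


def truncate_quench(curve: MeltCurve) -> MeltCurve:
    """Cut the curve at its global fluorescence maximum (inclusive).

    Post-maximum data are dominated by dye quenching and bias the sigmoid
    fit.  No-op when the maximum is the last point.
    """
    idx = int(np.argmax(curve.fluorescence))
    if idx == 0:
        raise DataError("fluorescence maximum at the first point: inverted curve?")
    if idx == len(curve) - 1:
        return curve
    return MeltCurve(curve.temperatures[: idx + 1],
                     curve.fluorescence[: idx + 1], curve.replicate_id)


def _boltzmann(T, bn, mn, bu, mu, tm, a):
    nat = bn + mn * T
    unf = bu + mu * T
    return nat + (unf - nat) / (1.0 + np.exp((tm - T) / a))


def _noise_scale(F: np.ndarray) -> float:
    """Noise sigma from second differences (signal curvature cancels)."""
    d2 = np.diff(F, n=2)
    return float(np.sqrt(np.mean(d2 ** 2) / 6.0)) if len(d2) else 0.0


def _smooth(F: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return F
    pad = window // 2
    Fp = np.concatenate([np.full(pad, F[0]), F, np.full(pad, F[-1])])
    return np.convolve(Fp, np.ones(window) / window, mode="valid")


def _half_crossing(T: np.ndarray, F: np.ndarray) -> float:
    """Robust Tm start value: half-amplitude crossing of a heavily
    smoothed curve (insensitive to point-level noise on dense grids)."""
    window = int(np.clip(len(F) // 20, 5, 101)) | 1
    Fs = _smooth(F, window)
    half = 0.5 * (Fs.min() + Fs.max())
    above = np.nonzero(Fs >= half)[0]
    idx = above[0] if len(above) else len(T) // 2
    return float(T[idx])


def fit_melt_sigmoid(curve: MeltCurve) -> MeltFitResult:
    """Boltzmann-sigmoid fit; Tm is the half-transition point by construction.

    Returns a flagged result (tm = nan, converged False) when the curve
    shows no transition (amplitude below 3x the noise scale).
    """
    T, F = curve.temperatures, curve.fluorescence
    noise = _noise_scale(F)
    amplitude = float(np.ptp(F))
    if amplitude < 3.0 * max(noise, 1e-30) or amplitude == 0.0:
        return MeltFitResult(math.nan, math.nan, (math.nan, math.nan),
                             (math.nan, math.nan), "sigmoid", noise, False,
                             message="no transition detected")

    n = len(T)
    n_edge = max(3, n // 10)
    reg_n = stats.linregress(T[:n_edge], F[:n_edge])
    reg_u = stats.linregress(T[-n_edge:], F[-n_edge:])
    tm0 = _half_crossing(T, F)
    grid = float(np.median(np.diff(T)))

    params = lmfit.Parameters()
    params.add("bn", value=reg_n.intercept)
    params.add("mn", value=reg_n.slope)
    params.add("bu", value=reg_u.intercept)
    params.add("mu", value=reg_u.slope)
    params.add("tm", value=tm0, min=float(T[0]), max=float(T[-1]))
    params.add("a", value=max(1.0, 2 * grid), min=0.01, max=(T[-1] - T[0]))

    def resid(p):
        return _boltzmann(T, p["bn"].value, p["mn"].value, p["bu"].value,
                          p["mu"].value, p["tm"].value, p["a"].value) - F

    res = lmfit.minimize(resid, params, method="leastsq")
    p = res.params
    rms = float(np.sqrt(np.mean(res.residual ** 2)))
    return MeltFitResult(
        tm=float(p["tm"].value), width=float(p["a"].value),
        baseline_native=(float(p["bn"].value), float(p["mn"].value)),
        baseline_unfolded=(float(p["bu"].value), float(p["mu"].value)),
        method="sigmoid", residual_rms=rms, converged=bool(res.success))


def tm_by_derivative(curve: MeltCurve, window: int = 5,
                     _validate: bool = True) -> float:
    """Temperature at the maximum of the smoothed first derivative dF/dT."""
    T, F = curve.temperatures, curve.fluorescence
    if _validate and len(T) < 20:
        raise DataError("derivative Tm needs at least 20 points")
    dF = np.gradient(_smooth(F, window), T)
    idx = int(np.argmax(dF))
    if idx == 0 or idx == len(T) - 1:
        raise DomainError("derivative maximum at the curve edge: no transition")
    return float(T[idx])
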