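"""Tight, slow-binding inhibition progress-curve analysis.

A slow-binding inhibitor I of an enzyme E produces biphasic product progress
curves: an initial velocity ``v0`` relaxes to a steady-state velocity ``vs``
with an observed rate constant ``k``.  When the inhibitor is *tight* —
comparable in concentration to the enzyme itself — free inhibitor is depleted
by binding and the classical exponential progress-curve model must be
corrected by the depletion factor

    gamma = Et * (1 - vs/v0)**2 / It,

which equals the ratio ``x1/x2`` of the two roots of the equilibrium binding
quadratic.  The absorbance progress curve then reads

    A(t) = vs*t + (1-gamma)*(v0-vs)/(k*gamma)
                * ln((1 - gamma*exp(-k*t)) / (1 - gamma)) + A0,

with the analytic limit ``A(t) = vs*t + (v0-vs)*(1-exp(-k*t))/k + A0`` as
``gamma -> 0`` (classical, non-tight case).

The apparent inhibition constant Ki' (in the presence of competing
substrate) follows from the Henderson linearization: plotting
``It/(1 - vs/v0)`` against ``v0/vs`` across an inhibitor dilution series
gives a straight line with slope Ki' and intercept equal to the total
enzyme concentration Et.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy import stats

from .errors import DomainError, DataError, FitError

__all__ = [
    "AssayDesign",
    "ProgressCurve",
    "ProgressFitResult",
    "HendersonResult",
    "SlowBindingParams",
    "gamma_of",
    "morrison_fraction",
    "eval_progress_model",
    "fit_progress_curve",
    "fit_uninhibited",
    "henderson_ki",
    "normalize_endpoint",
]

MIN_POINTS = 8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayDesign:
    """Chromogenic protease assay geometry and observation window.

    Concentrations are molar, times in seconds.  ``product_extinction`` is
    the molar extinction coefficient of the released chromophore
    (p-nitroaniline, 410 nm) in M^-1 cm^-1.  ``kcat`` and ``km`` describe
    substrate turnover by the free enzyme and are used by the simulator to
    set the uninhibited rate v0 = extinction*path*kcat*Et*S0/(Km+S0).
    """

    total_enzyme: float          # Et, M
    total_inhibitor: float       # It, M
    substrate_conc: float        # S0, M
    temperature: float = 25.0    # deg C
    duration: float = 1800.0     # s
    sampling_interval: float = 2.0   # s
    product_extinction: float = 8800.0   # M^-1 cm^-1 at 410 nm
    path_length: float = 1.0     # cm
    baseline_absorbance: float = 0.05    # A0
    kcat: float = 25.0           # s^-1
    km: float = 5.0e-4           # M

    def __post_init__(self) -> None:
        if self.total_enzyme <= 0:
            raise DomainError("total_enzyme must be > 0")
        if self.total_inhibitor < 0:
            raise DomainError("total_inhibitor must be >= 0")
        if self.substrate_conc <= 0 or self.duration <= 0:
            raise DomainError("substrate_conc and duration must be > 0")
        if self.sampling_interval <= 0:
            raise DomainError("sampling_interval must be > 0")
        if self.product_extinction <= 0 or self.path_length <= 0:
            raise DomainError("product_extinction and path_length must be > 0")

    @property
    def uninhibited_rate(self) -> float:
        """v0 in absorbance/s for the inhibitor-free reaction."""
        sat = self.substrate_conc / (self.km + self.substrate_conc)
        return (self.product_extinction * self.path_length
                * self.kcat * self.total_enzyme * sat)

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 0.5 * self.sampling_interval,
                         self.sampling_interval)


@dataclass(frozen=True)
class ProgressCurve:
    """One chromogenic time series at a fixed total inhibitor concentration."""

    curve_id: str
    inhibitor_conc: float        # It, M
    times: np.ndarray            # s, strictly increasing
    signal: np.ndarray           # absorbance at 410 nm

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise DataError(f"{self.curve_id}: times and signal must be 1-D and equal length")
        if len(t) < MIN_POINTS:
            raise DataError(f"{self.curve_id}: at least {MIN_POINTS} points required")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise DataError(f"{self.curve_id}: times must be strictly increasing, first >= 0")
        if not np.all(np.isfinite(a)):
            raise DataError(f"{self.curve_id}: signal contains non-finite values")
        if self.inhibitor_conc < 0:
            raise DataError(f"{self.curve_id}: inhibitor_conc must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ProgressFitResult:
    """Per-curve fit of the tight slow-binding model."""

    curve_id: str
    inhibitor_conc: float        # It, M (carried through for Henderson)
    v0: float                    # absorbance/s
    vs: float                    # absorbance/s
    k: float                     # s^-1
    A0: float                    # absorbance
    gamma: float
    residual_rms: float
    converged: bool
    n_points: int
    covariance: np.ndarray | None = None
    k_identifiable: bool = True
    message: str = ""


@dataclass
class HendersonResult:
    """Henderson-plot regression: slope = apparent Ki', intercept ~ Et."""

    ki_app: float                # M (slope)
    intercept: float             # M (theory: = Et)
    r_squared: float
    slope_stderr: float
    points: list = field(default_factory=list)   # (x = v0/vs, y = It/(1-vs/v0))
    n_curves: int = 0


@dataclass(frozen=True)
class SlowBindingParams:
    """Mechanistic one-step binding parameters (simulator ground truth).

    kon_app is the apparent association rate under competing substrate;
    the apparent inhibition constant is koff/kon_app.
    """

    kon_app: float               # M^-1 s^-1
    koff: float                  # s^-1

    def __post_init__(self) -> None:
        if self.kon_app <= 0:
            raise DomainError("kon_app must be > 0")
        if self.koff < 0:
            raise DomainError("koff must be >= 0")

    @property
    def ki_app(self) -> float:
        return self.koff / self.kon_app


# ---------------------------------------------------------------------------
# core algebra
# ---------------------------------------------------------------------------

def gamma_of(Et: float, It: float, v0: float, vs: float) -> float:
    """Depletion factor gamma = Et*(1 - vs/v0)**2 / It.

    Raises
    ------
    DomainError
        If any concentration/velocity is outside its domain, or if the
        computed gamma reaches 1 (which would place ln(0) or a negative
        argument into the progress-curve model; physically it means the
        stored velocities are inconsistent with finite-affinity binding).
    """
    if Et <= 0 or It <= 0 or v0 <= 0:
        raise DomainError("Et, It and v0 must all be > 0")
    if vs < 0 or vs > v0:
        raise DomainError("vs must satisfy 0 <= vs <= v0")
    g = Et * (1.0 - vs / v0) ** 2 / It
    if g >= 1.0:
        raise DomainError(
            f"gamma = {g:.6g} >= 1: infinitely tight / inconsistent velocities")
    return g


def binding_roots(Et: float, It: float, ki_app: float) -> tuple[float, float]:
    """Roots x1 <= x2 of x**2 - (Et + It + ki_app)*x + Et*It = 0.

    x1 is the equilibrium complex concentration; x2 is the spurious root.
    Computed in the numerically stable product form so x1 keeps full
    precision even when Et*It << b**2.
    """
    b = Et + It + ki_app
    disc = b * b - 4.0 * Et * It
    if disc < 0:
        raise DomainError("negative discriminant in binding quadratic")
    sq = math.sqrt(disc)
    x1 = 2.0 * Et * It / (b + sq)
    x2 = 0.5 * (b + sq)
    return x1, x2


def morrison_fraction(Et: float, It: float, ki_app: float) -> float:
    """Steady-state fractional velocity vs/v0 for tight binding.

    Solves the binding quadratic exactly (Morrison treatment), valid when
    inhibitor is depleted by binding.  Reduces to the classical
    1/(1 + It/Ki) as Et -> 0.
    """
    if Et <= 0:
        raise DomainError("Et must be > 0")
    if It < 0:
        raise DomainError("It must be >= 0")
    if ki_app <= 0:
        raise DomainError("ki_app must be > 0")
    if It == 0:
        return 1.0
    x1, _ = binding_roots(Et, It, ki_app)
    frac = (Et - x1) / Et
    return min(max(frac, 0.0), 1.0)


def eval_progress_model(v0: float, vs: float, k: float, A0: float,
                        gamma: float, t) -> np.ndarray | float:
    """Evaluate the tight slow-binding progress-curve model at time(s) t.

    Switches to the analytic gamma -> 0 limit when gamma is numerically
    zero (the logarithmic form is 0/0 there).
    """
    if not 0.0 <= gamma < 1.0:
        raise DomainError(f"gamma = {gamma} outside [0, 1)")
    if k <= 0:
        raise DomainError("k must be > 0")
    t_arr = np.asarray(t, dtype=float)
    e = np.exp(-k * t_arr)
    if gamma < 1e-14:
        out = vs * t_arr + (v0 - vs) * (1.0 - e) / k + A0
    else:
        # log1p keeps precision for small gamma; the prefactor divides by it
        ln_term = np.log1p(-gamma * e) - math.log1p(-gamma)
        out = vs * t_arr + (1.0 - gamma) * (v0 - vs) / (k * gamma) * ln_term + A0
    if np.isscalar(t):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_guesses(t: np.ndarray, a: np.ndarray) -> tuple[float, float, float, float]:
    """Heuristic (v0, vs, k, A0) start values.

    v0 from the slope of the first 10% of points, vs from the last 20%,
    k from a log-linear fit of the decay of the local slope toward vs,
    A0 from the first point.
    """
    n = len(t)
    n_head = max(3, n // 10)
    n_tail = max(3, n // 5)
    v0 = stats.linregress(t[:n_head], a[:n_head]).slope
    vs = stats.linregress(t[-n_tail:], a[-n_tail:]).slope
    v0 = max(v0, 1e-12)
    vs = min(max(vs, 0.0), v0)
    A0 = float(a[0])

    # local slopes via central differences, lightly smoothed
    slopes = np.gradient(a, t)
    if n >= 15:
        kern = np.ones(5) / 5.0
        slopes = np.convolve(slopes, kern, mode="same")
    excess = slopes - vs
    mask = excess > 0.05 * max(v0 - vs, 1e-15)
    k0 = 2.0 / t[-1] if t[-1] > 0 else 1e-3
    if mask.sum() >= 4 and v0 > vs:
        tt, yy = t[mask], np.log(excess[mask])
        sl = stats.linregress(tt, yy).slope
        if sl < 0:
            k0 = -sl
    return v0, vs, min(max(k0, 1e-6), 1.0), A0


def _tight_residual(params: lmfit.Parameters, t: np.ndarray, a: np.ndarray,
                    Et: float, It: float) -> np.ndarray:
    v0 = params["v0"].value
    f = params["f"].value
    k = params["k"].value
    A0 = params["A0"].value
    vs = f * v0
    g = Et * (1.0 - f) ** 2 / It
    g = min(g, 1.0 - 1e-9)   # keep the model evaluable; optimum lies below 1
    return eval_progress_model(v0, vs, k, A0, g, t) - a


def fit_progress_curve(curve: ProgressCurve, Et: float,
                       max_restarts: int = 5) -> ProgressFitResult:
    """Nonlinear least-squares fit of one inhibited progress curve.

    The depletion factor gamma is *not* a free parameter: it is recomputed
    from (Et, It, v0, vs) at every model evaluation, keeping the fit
    4-parameter and self-consistent.  vs is reparameterized as f*v0 with
    f in [0, 1] so vs <= v0 is enforced by construction.
    """
    if Et <= 0:
        raise DomainError("Et must be > 0")
    if curve.inhibitor_conc <= 0:
        raise FitError("It = 0 curves must go to fit_uninhibited")
    t, a = curve.times, curve.signal
    It = curve.inhibitor_conc

    v0g, vsg, kg, A0g = _initial_guesses(t, a)
    rng = np.random.default_rng(0)

    best = None
    for attempt in range(max_restarts):
        params = lmfit.Parameters()
        params.add("v0", value=v0g, min=0.0)
        params.add("f", value=min(max(vsg / v0g, 1e-6), 1.0), min=0.0, max=1.0)
        k_start = kg if attempt == 0 else float(
            np.clip(kg * 10.0 ** rng.uniform(-1.5, 1.5), 1e-6, 1.0))
        params.add("k", value=k_start, min=1e-6, max=1.0)
        params.add("A0", value=A0g)
        try:
            res = lmfit.minimize(_tight_residual, params, args=(t, a, Et, It),
                                 method="leastsq")
        except Exception:       # pragma: no cover - optimizer pathologies
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
        if res.success and best.chisqr <= res.chisqr * (1 + 1e-9):
            break

    if best is None:
        return ProgressFitResult(curve.curve_id, It, math.nan, math.nan,
                                 math.nan, math.nan, math.nan, math.nan,
                                 False, len(t), message="optimizer failed")

    v0 = best.params["v0"].value
    f = best.params["f"].value
    k = best.params["k"].value
    A0 = best.params["A0"].value
    vs = f * v0
    g = Et * (1.0 - f) ** 2 / It
    rms = float(np.sqrt(np.mean(best.residual ** 2)))
    cov = best.covar if best.covar is not None else None

    # vs ~ v0 means no inhibition transient: k carries no information
    k_ident = f < 0.999 and g > 0
    msg = "" if k_ident else "vs/v0 >= 0.999: k unidentifiable (uninhibited-looking trace)"

    return ProgressFitResult(
        curve_id=curve.curve_id, inhibitor_conc=It, v0=v0, vs=vs, k=k, A0=A0,
        gamma=min(g, 1.0 - 1e-9), residual_rms=rms,
        converged=bool(best.success), n_points=len(t), covariance=cov,
        k_identifiable=k_ident, message=msg)


def fit_uninhibited(curve: ProgressCurve, design: AssayDesign | None = None,
                    min_points: int = 10) -> float:
    """Linear slope v0 of an inhibitor-free progress curve.

    If an :class:`AssayDesign` is supplied, only the linear range is used:
    points where the accumulated signal is below 20% of the theoretical
    plateau ``extinction * path * S0`` above baseline (at least
    ``min_points`` points).  Without a design, all points are used.
    """
    if curve.inhibitor_conc != 0:
        raise FitError("fit_uninhibited requires an It = 0 curve")
    t, a = curve.times, curve.signal
    if design is not None:
        plateau = design.product_extinction * design.path_length * design.substrate_conc
        mask = (a - a[0]) < 0.2 * plateau
        if mask.sum() < min_points:
            mask = np.zeros_like(mask)
            mask[: min(min_points, len(t))] = True
        t, a = t[mask], a[mask]
    reg = stats.linregress(t, a)
    span = np.ptp(a)
    if span < 1e-12 or reg.slope <= 0:
        raise DataError("uninhibited curve has non-positive slope "
                        "(constant signal or inverted data?)")
    return float(reg.slope)


def henderson_ki(fits: list[ProgressFitResult], Et: float) -> HendersonResult:
    """Apparent inhibition constant from the Henderson linearization.

    Regresses y = It/(1 - vs/v0) on x = v0/vs with a *free* intercept; the
    slope is Ki' and the intercept is reported as a diagnostic (exact
    Henderson theory predicts intercept = Et).  Fits with vs = v0 carry no
    inhibition information and are excluded with a warning.
    """
    if Et <= 0:
        raise DomainError("Et must be > 0")
    pts = []
    for fr in fits:
        if not np.isfinite(fr.v0) or fr.v0 <= 0:
            continue
        if fr.vs >= fr.v0 * (1.0 - 1e-9) or fr.vs <= 0:
            warnings.warn(
                f"curve {fr.curve_id}: vs ~ v0, excluded from Henderson plot")
            continue
        x = fr.v0 / fr.vs
        y = fr.inhibitor_conc / (1.0 - fr.vs / fr.v0)
        pts.append((x, y, fr.inhibitor_conc))
    if len(pts) < 2:
        raise FitError("fewer than 2 usable curves for the Henderson plot")
    its = {round(p[2], 15) for p in pts}
    if len(its) < 2:
        raise FitError("Henderson regression needs >= 2 distinct inhibitor "
                       "concentrations (rank-deficient design)")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    reg = stats.linregress(x, y)
    if reg.slope <= 0:
        raise FitError("Henderson slope is non-positive; data inconsistent "
                       "with inhibition")
    return HendersonResult(
        ki_app=float(reg.slope), intercept=float(reg.intercept),
        r_squared=float(reg.rvalue ** 2), slope_stderr=float(reg.stderr),
        points=[(float(a), float(b)) for a, b, _ in pts], n_curves=len(pts))


def normalize_endpoint(test: ProgressCurve, reference: ProgressCurve
                       ) -> tuple[np.ndarray, float]:
    """Normalize a test curve to the final signal of its uninhibited reference.

    Returns the normalized signal series and the percent inhibition
    100*(1 - final normalized value), mirroring endpoint normalization of
    inhibition assays to the highest (final) absorbance of the
    inhibitor-free reaction.
    """
    ref_final = reference.signal[-1]
    if ref_final <= reference.signal[0]:
        raise DataError("reference final signal does not exceed its baseline")
    norm = test.signal / ref_final
    pct = 100.0 * (1.0 - float(norm[-1]))
    return norm, pct
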