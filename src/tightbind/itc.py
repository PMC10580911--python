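"""Independent-sites ITC isotherm: dilution bookkeeping, model heats, fitting.

Implements the single-class-of-sites (identical, non-interacting) binding
model for a displacement-cell titration calorimeter.  Each injection of
titrant X into the cell (species M, active volume V0) displaces cell
contents; the standard bookkeeping gives the effective cell concentrations
after a cumulative injected volume dV:

    Mt = M0 * (1 - dV/2V0) / (1 + dV/2V0)
    Xt = Xs * (dV/V0)      / (1 + dV/2V0)

The fraction of sites occupied, theta, solves the quadratic

    theta**2 - theta*(1 + Xt/(n*Mt) + Kd/(n*Mt)) + Xt/(n*Mt) = 0

(smaller root).  The cumulative heat after injection i is
Q_i = n*theta_i*Mt_i*dH*V0, and the differential (measured) heat corrects
for the heat carried out with the displaced volume:

    q_i = Q_i - Q_{i-1} + (dV_i/V0) * (Q_i + Q_{i-1})/2.

The Wiseman c-value ``c = n*M0/Kd`` is reported as a conditioning
diagnostic: Kd is well determined roughly for 1 < c < 1000.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

from .errors import DomainError, DataError, FitError

__all__ = [
    "TitrationDesign",
    "InjectionHeats",
    "BindingFit",
    "injection_concentrations",
    "expected_heats",
    "subtract_blank",
    "fit_itc",
    "c_value",
]


@dataclass(frozen=True)
class TitrationDesign:
    """Geometry of an ITC titration (SI units: litres, molar)."""

    cell_volume: float               # V0, L
    cell_conc: float                 # M0, molar (species in cell)
    syringe_conc: float              # Xs, molar (titrant)
    injection_volumes: tuple         # L each
    temperature: float = 25.0        # deg C

    def __post_init__(self) -> None:
        vols = tuple(float(v) for v in self.injection_volumes)
        object.__setattr__(self, "injection_volumes", vols)
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise DomainError("cell_volume, cell_conc, syringe_conc must be > 0")
        if not vols or any(v <= 0 for v in vols):
            raise DomainError("all injection volumes must be > 0")
        if sum(vols) >= self.cell_volume:
            raise DomainError("cumulative injected volume must stay below V0")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @classmethod
    def uniform(cls, cell_volume: float, cell_conc: float, syringe_conc: float,
                n_injections: int, injection_volume: float,
                temperature: float = 25.0) -> "TitrationDesign":
        return cls(cell_volume, cell_conc, syringe_conc,
                   tuple([injection_volume] * n_injections), temperature)


@dataclass
class InjectionHeats:
    """Integrated per-injection heats (J, exothermic negative)."""

    heats: np.ndarray
    blank_heats: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.blank_heats is not None:
            self.blank_heats = np.asarray(self.blank_heats, dtype=float)
            if self.blank_heats.shape != self.heats.shape:
                raise DataError("blank_heats length must match heats")

    @property
    def n_injections(self) -> int:
        return len(self.heats)


@dataclass
class BindingFit:
    """Fitted independent-sites parameters."""

    n_sites: float
    kd: float                    # M
    delta_h: float               # J/mol
    c_value: float
    residual_rms: float          # J
    converged: bool
    covariance: np.ndarray | None = None
    conditioning_warning: bool = False
    no_binding: bool = False
    message: str = ""


def injection_concentrations(design: TitrationDesign, i: int
                             ) -> tuple[float, float]:
    """Effective cell concentrations (Mt, Xt) after injection i (1-based)."""
    if not 1 <= i <= design.n_injections:
        raise DomainError(f"injection index {i} out of range")
    dv = sum(design.injection_volumes[:i])
    if dv >= design.cell_volume:
        raise DomainError("cumulative injected volume exceeds cell volume")
    r = dv / design.cell_volume
    mt = design.cell_conc * (1.0 - r / 2.0) / (1.0 + r / 2.0)
    xt = design.syringe_conc * r / (1.0 + r / 2.0)
    return mt, xt


def _theta(xt: float, mt: float, n: float, kd: float) -> float:
    """Smaller root of the occupancy quadratic, numerically stable."""
    r = xt / (n * mt)
    K = kd / (n * mt)
    b = 1.0 + r + K
    disc = b * b - 4.0 * r
    if disc < 0:
        raise DomainError("negative discriminant in occupancy quadratic")
    th = 2.0 * r / (b + math.sqrt(disc))
    if not -1e-12 <= th <= 1.0 + 1e-12:
        raise DomainError(f"occupancy theta = {th} outside [0, 1]")
    return min(max(th, 0.0), 1.0)


def expected_heats(n: float, kd: float, delta_h: float,
                   design: TitrationDesign,
                   dilution_correction: bool = True) -> np.ndarray:
    """Model per-injection heats (J) for the independent-sites isotherm."""
    if n <= 0 or kd <= 0:
        raise DomainError("n and kd must be > 0")
    v0 = design.cell_volume
    heats = np.empty(design.n_injections)
    q_prev = 0.0
    for i in range(1, design.n_injections + 1):
        mt, xt = injection_concentrations(design, i)
        th = _theta(xt, mt, n, kd)
        q = n * th * mt * delta_h * v0
        dq = q - q_prev
        if dilution_correction:
            dq += (design.injection_volumes[i - 1] / v0) * (q + q_prev) / 2.0
        heats[i - 1] = dq
        q_prev = q
    return heats


def subtract_blank(heats: InjectionHeats) -> InjectionHeats:
    """Element-wise blank subtraction; returns a new object with blank cleared."""
    if heats.blank_heats is None:
        raise DataError("no blank_heats present to subtract")
    return InjectionHeats(heats.heats - heats.blank_heats, None)


def c_value(n: float, cell_conc: float, kd: float) -> float:
    """Wiseman conditioning number c = n*M0/Kd."""
    return n * cell_conc / kd


def fit_itc(heats: InjectionHeats, design: TitrationDesign,
            init: dict | None = None, drop_first: bool = False,
            dilution_correction: bool = True) -> BindingFit:
    """Least-squares fit of (n, Kd, dH) to integrated injection heats.

    Kd is fitted in log10 space (positivity + scale invariance); unless an
    ``init`` dict provides start values, a small multi-start over Kd
    decades guards against the isotherm's flat directions at extreme c.
    ``drop_first`` discards the first injection (common practice when the
    syringe tip equilibrates diffusively before the run).
    """
    if heats.blank_heats is not None:
        heats = subtract_blank(heats)
    q = heats.heats.copy()
    if drop_first:
        # keep the dilution bookkeeping consistent: injection 1 still
        # happened, its heat is simply not scored
        q = q[1:]
    if len(q) < 6:
        raise FitError("at least 6 usable injections required")
    ratios = [injection_concentrations(design, i + 1)[1] /
              injection_concentrations(design, i + 1)[0]
              for i in range(design.n_injections)]
    if len(set(np.round(ratios, 12))) < 3:
        raise FitError("fewer than 3 distinct molar-ratio points")

    moles_per_inj = design.syringe_conc * design.injection_volumes[0]
    dh0 = q[0] / moles_per_inj
    if dh0 == 0:
        dh0 = -1.0
    n0 = init.get("n", 1.0) if init else 1.0
    dh0 = init.get("delta_h", dh0) if init else dh0
    if init and "kd" in init:
        kd_starts = [init["kd"]]
    else:
        kd_starts = [10.0 ** e for e in (-10, -9, -8, -7, -6, -5)]

    best = None
    for kd0 in kd_starts:
        params = lmfit.Parameters()
        params.add("n", value=n0, min=1e-3, max=100.0)
        params.add("log10_kd", value=math.log10(kd0), min=-14.0, max=0.0)
        params.add("dh", value=dh0)

        def resid_fn(p):
            model = expected_heats(p["n"].value, 10.0 ** p["log10_kd"].value,
                                   p["dh"].value, design, dilution_correction)
            if drop_first:
                model = model[1:]
            return model - q

        try:
            res = lmfit.minimize(resid_fn, params, method="leastsq")
        except Exception:       # pragma: no cover
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None:
        return BindingFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                          False, message="optimizer failed")

    n = best.params["n"].value
    kd = 10.0 ** best.params["log10_kd"].value
    dh = best.params["dh"].value
    rms = float(np.sqrt(np.mean(best.residual ** 2)))
    c = c_value(n, design.cell_conc, kd)

    cond = c > 1000.0 or c < 1.0
    if cond:
        warnings.warn(f"ITC c-value = {c:.3g} outside [1, 1000]: "
                      "Kd weakly identified", stacklevel=2)

    # no-binding check: total observed heat indistinguishable from noise,
    # with the noise scale taken from first differences (the isotherm is
    # smooth, so diffs are noise-dominated when there is no binding)
    sigma_hat = math.sqrt(float(np.mean(np.diff(q) ** 2)) / 2.0)
    no_binding = bool(abs(q.sum()) < 3.0 * sigma_hat * math.sqrt(len(q)))

    return BindingFit(n_sites=n, kd=kd, delta_h=dh, c_value=c,
                      residual_rms=rms, converged=bool(best.success),
                      covariance=best.covar, conditioning_warning=cond,
                      no_binding=no_binding)
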