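"""Mechanistic generators for every assay the pipeline fits.

Progress curves come from the one-step slow-binding scheme
E + I <-> EI (kon_app, koff) with free-substrate product accumulation
dP/dt = v_spec * (Et - EI)/Et.  Two independent routes are provided:

* ``analytic`` — the Riccati closed form for the complex,
  ``x(t) = x1*(1 - exp(-k t)) / (1 - (x1/x2)*exp(-k t))`` with
  ``k = kon_app*(x2 - x1)``, whose product integral is evaluated in
  closed form;
* ``ode`` — stiff numerical integration of the same scheme with
  :func:`scipy.integrate.solve_ivp`, used as the cross-validation oracle
  (and the only route offering substrate depletion).

ITC heats come from :func:`tightbind.itc.expected_heats` at the titration
geometry, and DSF ramps from a Boltzmann sigmoid with linear baselines and
an optional post-transition exponential dye-quench term.

All generators are pure functions of (fixture, seed): the same seed yields
bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError
from .progress import (AssayDesign, ProgressCurve, SlowBindingParams,
                       binding_roots, eval_progress_model)
from .itc import TitrationDesign, InjectionHeats, expected_heats
from .dsf import MeltCurve
from .fixtures import Fixture, load_fixture

__all__ = [
    "SimNoise",
    "simulate_progress_curve",
    "simulate_inhibition_series",
    "simulate_itc",
    "simulate_melt",
]


@dataclass(frozen=True)
class SimNoise:
    """Noise magnitudes for the three assay classes.

    Multiplicative Gaussian for optical signals (absorbance,
    fluorescence), additive Gaussian for injection heats.
    """

    progress_rel_sigma: float = 0.01
    itc_abs_sigma: float = 0.2e-6      # J
    dsf_rel_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.progress_rel_sigma, self.itc_abs_sigma,
               self.dsf_rel_sigma) < 0:
            raise DomainError("noise sigmas must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "SimNoise":
        return SimNoise(self.progress_rel_sigma, self.itc_abs_sigma,
                        self.dsf_rel_sigma, seed)


ZERO_NOISE = SimNoise(0.0, 0.0, 0.0, 0)


# ---------------------------------------------------------------------------
# progress curves
# ---------------------------------------------------------------------------

def _map_to_observables(params: SlowBindingParams, design: AssayDesign
                        ) -> tuple[float, float, float, float]:
    """(v0, vs, k, gamma) of the progress-curve model for one mechanism."""
    Et, It = design.total_enzyme, design.total_inhibitor
    v0 = design.uninhibited_rate
    # koff = 0 gives ki_app = 0: roots of x^2 - (Et+It)x + Et*It are Et, It
    x1, x2 = binding_roots(Et, It, params.ki_app)
    k = params.kon_app * (x2 - x1)
    vs = v0 * (Et - x1) / Et
    gamma = x1 / x2
    return v0, vs, k, gamma


def _progress_ode(params: SlowBindingParams, design: AssayDesign,
                  t_eval: np.ndarray, depletion: bool = False
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate [EI](t) and product P(t); returns (EI, P) in molar."""
    Et, It = design.total_enzyme, design.total_inhibitor
    kon, koff = params.kon_app, params.koff
    kcat, km, S0 = design.kcat, design.km, design.substrate_conc

    if depletion:
        def rhs(t, y):
            ei, p, s = y
            free_e = Et - ei
            dei = kon * free_e * (It - ei) - koff * ei
            dp = kcat * free_e * s / (km + s)
            return [dei, dp, -dp]
        y0 = [0.0, 0.0, S0]
    else:
        vfac = kcat * S0 / (km + S0)

        def rhs(t, y):
            ei, p = y
            free_e = Et - ei
            dei = kon * free_e * (It - ei) - koff * ei
            return [dei, vfac * free_e]
        y0 = [0.0, 0.0]

    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), y0, t_eval=t_eval,
                    method="LSODA", rtol=1e-11, atol=1e-16)
    if not sol.success:
        raise RuntimeError(f"progress ODE integration failed: {sol.message}")
    return sol.y[0], sol.y[1]


def simulate_progress_curve(params: SlowBindingParams, design: AssayDesign,
                            noise: SimNoise = ZERO_NOISE,
                            mode: Literal["analytic", "ode"] = "analytic",
                            depletion: bool = False,
                            curve_id: str | None = None) -> ProgressCurve:
    """Simulate one A410 progress curve for the given mechanism and design."""
    t = design.times()
    eps_l = design.product_extinction * design.path_length
    v0 = design.uninhibited_rate

    # free-substrate validity: warn when >10% of S0 would be consumed
    approx_depl = v0 * design.duration / (eps_l * design.substrate_conc)
    if not depletion and approx_depl > 0.10:
        warnings.warn(f"free-substrate approximation strained: ~"
                      f"{100 * approx_depl:.0f}% substrate consumption "
                      "over the observation window", stacklevel=2)

    if design.total_inhibitor == 0:
        a = design.baseline_absorbance + v0 * t
    elif mode == "analytic":
        if depletion:
            raise DomainError("substrate depletion requires mode='ode'")
        v0_, vs, k, gamma = _map_to_observables(params, design)
        if gamma >= 1.0:       # koff = 0 with It >= Et: strict titration
            gamma = 1.0 - 1e-12
        a = eval_progress_model(v0_, vs, k, design.baseline_absorbance, gamma, t)
    elif mode == "ode":
        _, p = _progress_ode(params, design, t, depletion=depletion)
        a = design.baseline_absorbance + eps_l * p
    else:
        raise DomainError(f"unknown mode {mode!r}")

    if noise.progress_rel_sigma > 0:
        a = a * (1.0 + noise.progress_rel_sigma
                 * noise.rng().standard_normal(len(t)))

    cid = curve_id or f"It_{design.total_inhibitor * 1e9:g}nM"
    return ProgressCurve(cid, design.total_inhibitor, t, a)


def simulate_inhibition_series(fixture: Fixture | str,
                               noise: SimNoise = ZERO_NOISE,
                               mode: Literal["analytic", "ode"] = "analytic"
                               ) -> list[ProgressCurve]:
    """One progress curve per inhibitor concentration in the fixture grid.

    Child seeds are spawned deterministically from ``noise.seed`` so the
    whole series is reproducible from a single integer.
    """
    fx = load_fixture(fixture) if isinstance(fixture, str) else fixture
    if fx.kind != "progress":
        raise DomainError(f"fixture {fx.name} is not a progress fixture")
    params = SlowBindingParams(kon_app=fx.truth["kon_app"],
                               koff=fx.truth["ki_app"] * fx.truth["kon_app"])
    seeds = np.random.SeedSequence(noise.seed).generate_state(
        len(fx.inhibitor_grid))
    curves = []
    for it, child_seed in zip(fx.inhibitor_grid, seeds):
        design = fx.make_progress_design(it)
        nz = noise.with_seed(int(child_seed) % (2 ** 31))
        curves.append(simulate_progress_curve(params, design, nz, mode=mode))
    return curves


# ---------------------------------------------------------------------------
# ITC and DSF
# ---------------------------------------------------------------------------

def simulate_itc(fixture: Fixture | str, noise: SimNoise = ZERO_NOISE,
                 blank_offset: float | None = None) -> InjectionHeats:
    """Integrated injection heats for an ITC fixture (+ optional blank).

    ``blank_offset`` adds a constant dilution heat (J) to every injection
    and returns it in ``blank_heats`` so that blank subtraction can be
    exercised round-trip.
    """
    fx = load_fixture(fixture) if isinstance(fixture, str) else fixture
    if fx.kind != "itc":
        raise DomainError(f"fixture {fx.name} is not an itc fixture")
    design = fx.make_titration_design()
    q = expected_heats(fx.truth["n"], fx.truth["kd"], fx.truth["delta_h"],
                       design)
    blank = None
    if blank_offset is not None:
        q = q + blank_offset
        blank = np.full_like(q, blank_offset)
    if noise.itc_abs_sigma > 0:
        q = q + noise.itc_abs_sigma * noise.rng().standard_normal(len(q))
    return InjectionHeats(q, blank)


def simulate_melt(fixture: Fixture | str, noise: SimNoise = ZERO_NOISE,
                  quench: bool = True, replicate_id: str = "rep1"
                  ) -> MeltCurve:
    """Boltzmann melt on the instrument ramp grid, optional quench tail.

    The quench multiplies the signal by ``exp(-(T - Tq)/tau)`` for
    temperatures above ``Tq = Tm + 3a``, emulating post-transition dye
    quenching; it is what makes :func:`tightbind.dsf.truncate_quench`
    necessary on realistic data.
    """
    fx = load_fixture(fixture) if isinstance(fixture, str) else fixture
    if fx.kind != "dsf":
        raise DomainError(f"fixture {fx.name} is not a dsf fixture")
    ramp = fx.ramp
    step = ramp["rate"] * ramp["sample_every"]
    T = np.arange(ramp["t_start"], ramp["t_end"] + 0.5 * step, step)
    tm, a = fx.truth["tm"], fx.truth["width"]
    bl = fx.baselines
    nat = bl["native_intercept"] + bl["native_slope"] * T
    unf = bl["unfolded_intercept"] + bl["unfolded_slope"] * T
    F = nat + (unf - nat) / (1.0 + np.exp((tm - T) / a))
    if quench:
        tq = tm + 3.0 * a
        tau = fx.quench_tau
        F = F * np.exp(-np.clip(T - tq, 0.0, None) / tau)
    if noise.dsf_rel_sigma > 0:
        F = F * (1.0 + noise.dsf_rel_sigma
                 * noise.rng().standard_normal(len(T)))
    return MeltCurve(T, F, replicate_id)
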