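"""Small published-formula helpers used around the main analyses."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "SpectroSample",
    "molar_ellipticity",
    "azocasein_activity",
    "azocasein_activity_stats",
    "conc_from_a280",
]


@dataclass(frozen=True)
class SpectroSample:
    """Spectroscopy sample description for unit conversions."""

    concentration: float             # g/L (= mg/mL)
    path_length: float               # cm
    mean_residue_weight: float = 102.4   # g/mol
    extinction_coeff_280: float | None = None  # M^-1 cm^-1

    def __post_init__(self) -> None:
        if self.concentration <= 0 or self.path_length <= 0:
            raise DomainError("concentration and path_length must be > 0")
        if self.mean_residue_weight <= 0:
            raise DomainError("mean_residue_weight must be > 0")
        if self.extinction_coeff_280 is not None and self.extinction_coeff_280 <= 0:
            raise DomainError("extinction_coeff_280 must be > 0")


def molar_ellipticity(theta_obs: float, sample: SpectroSample) -> float:
    """Mean-residue molar ellipticity in deg cm^2 dmol^-1.

    [theta] = theta_obs * MRW / (10 * l * c) with theta_obs in
    millidegrees, c in g/L and l in cm.
    """
    return (theta_obs * sample.mean_residue_weight
            / (10.0 * sample.path_length * sample.concentration))


def azocasein_activity(sample_a440: float, control_a440: float) -> float:
    """Control-subtracted azocasein proteolysis readout.

    Negative values are meaningful: they indicate inhibition of the
    control protease by the added zymogen.
    """
    if not (math.isfinite(sample_a440) and math.isfinite(control_a440)):
        raise DomainError("absorbance inputs must be finite")
    return sample_a440 - control_a440


def azocasein_activity_stats(sample_a440, control_a440) -> tuple[float, float]:
    """Mean and propagated sd of control-subtracted replicate readouts.

    For independent replicate sets the variance of the difference is the
    sum of the two population variances.
    """
    s = np.asarray(sample_a440, dtype=float)
    c = np.asarray(control_a440, dtype=float)
    mean = float(s.mean() - c.mean())
    sd = float(math.sqrt(s.var(ddof=0) + c.var(ddof=0)))
    return mean, sd


def conc_from_a280(a280: float, extinction: float, path: float = 1.0) -> float:
    """Beer-Lambert concentration c = A / (eps * l), in molar."""
    if extinction <= 0 or path <= 0:
        raise DomainError("extinction and path must be > 0")
    return a280 / (extinction * path)
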