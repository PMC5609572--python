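"""Synthetic beam model: analytic pristine Bragg curves and lateral profiles.

The pristine depth-dose curve is built from the CSDA form — dose at depth z
proportional to the stopping power at the local residual energy,
D(z) ∝ S(E(z)) — convolved with a Gaussian range-straggling kernel of width
σ = c·R^0.935 (c = 0.012 by default, R the CSDA range in mm). This
reproduces the canonical shape of a clinical low-energy proton peak: a low
entrance plateau, a sharp peak near end of range and a sub-millimetre
distal falloff. Lateral profiles are flat-top curves with error-function
shoulders, the standard model for a double-scattered, collimated field.

The generator is the test bed for every downstream module: seeded,
deterministic and file-round-trippable, so no measured scan is ever needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import erf

from . import physics
from .physics import WATER, MaterialSlab, water_equivalent_slab

__all__ = [
    "PristinePeak",
    "LateralProfileModel",
    "DEFAULT_STRAGGLING_COEFF",
    "pristine_bragg",
    "apply_range_shifter",
    "lateral_profile",
]

#: default coefficient c in σ = c · R^0.935 (mm), range straggling width
DEFAULT_STRAGGLING_COEFF = 0.012

#: exponent of the straggling power law
STRAGGLING_EXPONENT = 0.935


@dataclass
class PristinePeak:
    """A pristine Bragg curve on a uniform depth grid.

    ``depth_mm`` is 0-based at the phantom surface, strictly increasing and
    uniform; ``dose`` is non-negative with a single global maximum and is
    normalized to peak = 1; ``range90_mm`` caches the distal 90% depth.
    """

    depth_mm: np.ndarray
    dose: np.ndarray
    nominal_energy: float
    range90_mm: float = field(default=None)

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.depth_mm.shape != self.dose.shape:
            raise ValueError("depth and dose grids differ in length")
        steps = np.diff(self.depth_mm)
        if np.any(steps <= 0):
            raise ValueError("depth grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("depth grid must be uniform")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")
        if self.range90_mm is None:
            self.range90_mm = _distal_crossing(
                self.depth_mm, self.dose, 0.9 * self.dose.max()
            )

    @property
    def grid_step(self) -> float:
        return float(self.depth_mm[1] - self.depth_mm[0])


def _distal_crossing(z: np.ndarray, d: np.ndarray, level: float) -> float:
    """Deepest downward crossing of *level*, linear interpolation."""
    above = d >= level
    idx = np.nonzero(above[:-1] & ~above[1:])[0]
    if idx.size == 0:
        return float("nan")
    i = idx[-1]
    f = (d[i] - level) / (d[i] - d[i + 1])
    return float(z[i] + f * (z[i + 1] - z[i]))


def pristine_bragg(
    E: float,
    grid_step: float = 0.05,
    straggling_factor: float = DEFAULT_STRAGGLING_COEFF,
    tail_mm: float = 3.0,
) -> PristinePeak:
    """Analytic pristine Bragg curve for a proton beam of energy *E* (MeV).

    Parameters
    ----------
    E : float
        Beam kinetic energy, 10-250 MeV.
    grid_step : float
        Depth sampling in mm; must be ≤ 0.1 mm (clinical scan resolution).
    straggling_factor : float
        Coefficient c of the straggling width σ = c·R^0.935 mm. Pass 0 for
        the raw (unconvolved) CSDA curve.
    tail_mm : float
        Extra depth beyond the range kept on the grid.

    Returns
    -------
    PristinePeak with dose normalized to peak = 1.
    """
    if not (10.0 <= E <= 250.0):
        raise physics.EnergyDomainError("beam energy must be in [10, 250] MeV")
    if grid_step > 0.1:
        raise ValueError("grid_step must be ≤ 0.1 mm")
    R = physics.csda_range_mm(E, WATER)
    sigma = straggling_factor * R**STRAGGLING_EXPONENT
    if 0.0 < sigma < grid_step:
        warnings.warn(
            "straggling width below grid step; clamping to one step",
            stacklevel=2,
        )
        sigma = grid_step
    z = np.arange(0.0, R + tail_mm + 5.0 * sigma, grid_step)
    # residual range in g/cm² at each depth; E(z) via range inversion
    res = (R - z) * WATER.density / 10.0
    inside = res > physics.csda_range(physics.E_MIN, WATER)
    dose = np.zeros_like(z)
    e_res = physics.energy_at_range(res[inside], WATER)
    dose[inside] = physics.stopping_power_kev_um(e_res, WATER)
    if sigma > 0.0:
        dose = gaussian_filter1d(dose, sigma / grid_step, mode="constant")
    dose /= dose.max()
    return PristinePeak(z, dose, nominal_energy=E)


def apply_range_shifter(
    peak_source_energy: float,
    shifter_thickness_mm: float,
    grid_step: float = 0.05,
    straggling_factor: float = DEFAULT_STRAGGLING_COEFF,
    depth_grid: np.ndarray | None = None,
) -> PristinePeak:
    """Pristine peak after a water-equivalent range shifter.

    The shifter degrades the beam energy by CSDA slowing through a water
    slab; the returned peak's range90 is the unshifted range90 minus the
    shifter thickness (to within a couple of grid steps). Passing
    ``depth_grid`` resamples the curve onto a common grid (for SOBP work).
    """
    if shifter_thickness_mm < 0:
        raise ValueError("shifter thickness must be non-negative")
    if shifter_thickness_mm == 0.0:
        peak = pristine_bragg(peak_source_energy, grid_step, straggling_factor)
    else:
        R = physics.csda_range_mm(peak_source_energy, WATER)
        if shifter_thickness_mm >= R:
            raise ValueError("beam fully stopped: shifter exceeds beam range")
        try:
            e_out = physics.degrade_energy(
                peak_source_energy,
                [water_equivalent_slab(shifter_thickness_mm)],
            )
        except physics.StoppedInSlabError as exc:
            raise ValueError("beam fully stopped in range shifter") from exc
        if e_out < 10.0:
            raise ValueError("beam fully stopped: residual energy below model floor")
        peak = pristine_bragg(e_out, grid_step, straggling_factor)
    if depth_grid is not None:
        dose = np.interp(depth_grid, peak.depth_mm, peak.dose, left=0.0, right=0.0)
        peak = PristinePeak(np.asarray(depth_grid, float), dose,
                            nominal_energy=peak.nominal_energy)
    return peak


@dataclass(frozen=True)
class LateralProfileModel:
    """Flat-top lateral field with erf shoulders.

    field_radius is the half-width a of the flat top (mm), penumbra_sigma
    the Gaussian edge width σ (mm) — the 80-20% penumbra equals 1.683σ.
    asymmetry_factor scales the x > 0 half (1.0 = symmetric);
    noise_sigma is a multiplicative Gaussian noise fraction, seeded.
    """

    field_radius: float
    penumbra_sigma: float
    asymmetry_factor: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_radius <= 0:
            raise ValueError("field_radius must be positive")
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be positive")
        if self.asymmetry_factor <= 0:
            raise ValueError("asymmetry_factor must be positive")


def lateral_profile(x_grid: np.ndarray, model: LateralProfileModel) -> np.ndarray:
    """Dose (a.u.) at each lateral position of *x_grid* (mm, uniform).

    D(x) = ½[erf((x+a)/(σ√2)) − erf((x−a)/(σ√2))], the convolution of an
    ideal rectangle of half-width a with a Gaussian of width σ; the x > 0
    half is scaled by the asymmetry factor, then seeded multiplicative
    noise is applied.
    """
    x = np.asarray(x_grid, dtype=float)
    a, s = model.field_radius, model.penumbra_sigma
    dose = 0.5 * (erf((x + a) / (s * np.sqrt(2.0)))
                  - erf((x - a) / (s * np.sqrt(2.0))))
    if model.asymmetry_factor != 1.0:
        dose = np.where(x > 0, dose * model.asymmetry_factor, dose)
    if model.noise_sigma > 0:
        rng = np.random.default_rng(model.seed)
        dose = dose * (1.0 + model.noise_sigma * rng.standard_normal(x.shape))
        dose = np.clip(dose, 0.0, None)
    return dose
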