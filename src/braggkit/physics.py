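"""Proton stopping power, range-energy relations and slab energy degradation.

Everything downstream (Bragg curves, SOBP design, LET averaging) is built on
the electronic mass stopping power S(E) of protons and the CSDA
(continuous-slowing-down approximation) range R(E) = integral dE'/S(E').

Two evaluation modes are supported:

* ``bethe`` — the relativistic Bethe formula without shell or density
  corrections, adequate for protons between ~1 and 250 MeV in low-Z media,
* ``table`` — log-log interpolation of a user-supplied (energy, mass
  stopping power) table, so any published water table can be swapped in.

Units contract: energies in MeV, depths in mm, slab thicknesses in µm,
mass stopping power in MeV·cm²/g, linear stopping power in keV/µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StoppingPowerModel",
    "MaterialSlab",
    "WATER",
    "KAPTON",
    "TANTALUM",
    "E_MIN",
    "E_MAX",
    "stopping_power",
    "stopping_power_kev_um",
    "csda_range",
    "csda_range_mm",
    "energy_at_range",
    "degrade_energy",
    "water_equivalent_slab",
    "read_stopping_table",
    "write_stopping_table",
    "EnergyDomainError",
    "StoppedInSlabError",
]

# physical constants (CODATA)
PROTON_MASS_MEV = 938.27208816
ELECTRON_MASS_MEV = 0.51099895000
#: Bethe prefactor 4*pi*N_A*r_e^2*m_e*c^2 in MeV·cm²/mol
K_BETHE = 0.307075

#: supported kinetic-energy window, MeV
E_MIN = 0.1
E_MAX = 300.0

_RANGE_GRID_POINTS = 4000


class EnergyDomainError(ValueError):
    """Kinetic energy outside the supported window."""


class StoppedInSlabError(ValueError):
    """The proton does not have enough energy to traverse a slab."""


@dataclass
class StoppingPowerModel:
    """Electronic stopping-power model for protons in one material.

    Parameters
    ----------
    material_name : str
        Human-readable material label.
    density : float
        Mass density in g/cm³; must be positive.
    mean_excitation_energy : float
        Mean excitation energy I in eV; must be positive.
    z_over_a : float
        Ratio of atomic number to mass number, mol/g-flavoured and
        dimensionless for our purposes.
    mode : str
        ``"bethe"`` (closed form) or ``"table"`` (log-log interpolation).
    table : list of (float, float), optional
        (energy MeV, mass stopping power MeV·cm²/g) pairs, strictly
        increasing in energy; required in table mode.
    """

    material_name: str
    density: float
    mean_excitation_energy: float
    z_over_a: float
    mode: str = "bethe"
    table: list | None = None
    _range_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.mean_excitation_energy <= 0:
            raise ValueError("mean excitation energy must be positive")
        if self.mode not in ("bethe", "table"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "table":
            if not self.table:
                raise ValueError("table mode requires a stopping-power table")
            arr = np.asarray(self.table, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("table must be (energy, stopping power) pairs")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError("table energies must be strictly increasing")
            if np.any(arr <= 0):
                raise ValueError("table entries must be strictly positive")
            self._log_e = np.log(arr[:, 0])
            self._log_s = np.log(arr[:, 1])


#: liquid water with the ICRU-standard mean excitation energy
WATER = StoppingPowerModel("water", density=1.0, mean_excitation_energy=75.0,
                           z_over_a=0.5551)
#: Kapton polyimide film (C22 H10 N2 O5)
KAPTON = StoppingPowerModel("kapton", density=1.42, mean_excitation_energy=79.6,
                            z_over_a=0.5126)
#: tantalum scattering foil
TANTALUM = StoppingPowerModel("tantalum", density=16.654,
                              mean_excitation_energy=718.0, z_over_a=0.4034)


@dataclass(frozen=True)
class MaterialSlab:
    """A thin uniform absorber: material plus thickness in µm."""

    material: StoppingPowerModel
    thickness_um: float

    def __post_init__(self) -> None:
        if self.thickness_um < 0:
            raise ValueError("slab thickness must be non-negative")


def _check_energy(E) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if np.any(E < E_MIN) or np.any(E > E_MAX):
        raise EnergyDomainError(
            f"kinetic energy outside supported range [{E_MIN}, {E_MAX}] MeV"
        )
    return E


def _bethe_mass_stopping(E: np.ndarray, model: StoppingPowerModel) -> np.ndarray:
    gamma = 1.0 + E / PROTON_MASS_MEV
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    I_mev = model.mean_excitation_energy * 1e-6
    arg = 2.0 * ELECTRON_MASS_MEV * beta2 * gamma * gamma / I_mev
    return K_BETHE * model.z_over_a / beta2 * (np.log(arg) - beta2)


def stopping_power(E, model: StoppingPowerModel = WATER):
    """Mass stopping power S(E) in MeV·cm²/g.

    Accepts scalars or arrays; raises :class:`EnergyDomainError` outside
    [0.1, 300] MeV. In table mode, interpolates log S vs log E.
    """
    E = _check_energy(E)
    if model.mode == "bethe":
        out = _bethe_mass_stopping(E, model)
    else:
        out = np.exp(np.interp(np.log(E), model._log_e, model._log_s))
    return out if out.ndim else float(out)


def stopping_power_kev_um(E, model: StoppingPowerModel = WATER):
    """Linear stopping power in keV/µm (= MeV·cm²/g × ρ[g/cm³] / 10)."""
    s = stopping_power(E, model)
    return s * model.density * 0.1


def _range_table(model: StoppingPowerModel):
    """Cached (E grid, cumulative CSDA range g/cm²) pair for *model*.

    The cumulative trapezoid of 1/S on a fine log-spaced grid makes
    ``csda_range`` and ``energy_at_range`` exact mutual inverses: both are
    linear interpolations sharing the same breakpoints.
    """
    key = "range"
    if key not in model._range_cache:
        e = np.geomspace(E_MIN, E_MAX, _RANGE_GRID_POINTS)
        inv_s = 1.0 / stopping_power(e, model)
        r = np.concatenate(
            ([0.0], np.cumsum(np.diff(e) * 0.5 * (inv_s[1:] + inv_s[:-1])))
        )
        model._range_cache[key] = (e, r)
    return model._range_cache[key]


def csda_range(E, model: StoppingPowerModel = WATER):
    """CSDA range in g/cm², measured from the 0.1 MeV cutoff.

    R(E) = ∫ dE'/S(E'); the sub-0.1 MeV tail (a few µm of water) is
    neglected. Strictly increasing in E.
    """
    E = _check_energy(E)
    grid_e, grid_r = _range_table(model)
    out = np.interp(E, grid_e, grid_r)
    return out if out.ndim else float(out)


def csda_range_mm(E, model: StoppingPowerModel = WATER):
    """CSDA range in mm of the material (g/cm² ÷ ρ × 10)."""
    r = csda_range(E, model)
    return r / model.density * 10.0


def energy_at_range(R, model: StoppingPowerModel = WATER):
    """Kinetic energy (MeV) whose CSDA range equals *R* (g/cm²).

    Inverse of :func:`csda_range` on the shared grid; raises for R outside
    the tabulated span.
    """
    R = np.asarray(R, dtype=float)
    grid_e, grid_r = _range_table(model)
    if np.any(R < 0) or np.any(R > grid_r[-1]):
        raise EnergyDomainError("residual range outside tabulated span")
    out = np.interp(R, grid_r, grid_e)
    return out if out.ndim else float(out)


def degrade_energy(E_in: float, slabs) -> float:
    """Residual kinetic energy after CSDA slowing through *slabs* in order.

    Each slab removes its areal density from the proton's residual range in
    that material. A zero-thickness slab is the identity. Raises
    :class:`StoppedInSlabError` when the proton ranges out inside a slab.
    """
    E = float(_check_energy(E_in))
    for slab in slabs:
        if slab.thickness_um == 0.0:
            continue
        mat = slab.material
        areal = slab.thickness_um * 1e-4 * mat.density  # g/cm²
        residual = csda_range(E, mat) - areal
        if residual <= csda_range(E_MIN, mat):
            raise StoppedInSlabError(
                f"proton stopped in {mat.material_name} "
                f"({slab.thickness_um:g} µm slab, entry {E:.3f} MeV)"
            )
        E = energy_at_range(residual, mat)
    return E


def water_equivalent_slab(thickness_mm: float) -> MaterialSlab:
    """Water slab of *thickness_mm* (mm), the range-shifter primitive."""
    return MaterialSlab(WATER, thickness_mm * 1000.0)


def write_stopping_table(path, model: StoppingPowerModel, energies=None) -> None:
    """Write a two-column (MeV, MeV·cm²/g) stopping table with a # header."""
    if energies is None:
        energies = np.geomspace(E_MIN, E_MAX, 500)
    energies = np.asarray(energies, dtype=float)
    s = stopping_power(energies, model)
    with open(path, "w") as fh:
        fh.write(f"# name: {model.material_name}\n")
        fh.write(f"# density: {model.density!r}\n")
        fh.write(f"# I: {model.mean_excitation_energy!r}\n")
        fh.write(f"# z_over_a: {model.z_over_a!r}\n")
        fh.write("# columns: energy_MeV mass_stopping_power_MeV_cm2_g\n")
        for e, v in zip(energies, np.atleast_1d(s)):
            fh.write(f"{float(e)!r} {float(v)!r}\n")


def read_stopping_table(path) -> StoppingPowerModel:
    """Read a stopping table written by :func:`write_stopping_table`."""
    meta = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            rows.append((float(parts[0]), float(parts[1])))
    try:
        name = meta.get("name", "table")
        density = float(meta["density"])
        i_ev = float(meta["I"])
        z_over_a = float(meta.get("z_over_a", math.nan))
    except KeyError as exc:
        raise ValueError(f"missing header field {exc} in {path}") from exc
    return StoppingPowerModel(name, density, i_ev, z_over_a,
                              mode="table", table=rows)
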