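"""Track- and dose-averaged LET versus depth from fluence spectra.

At every depth the local radiation field is a fluence spectrum φ_i over
energy bins and particle species. With S_i the unrestricted LET (water
stopping power) at each bin centre, the two standard averages are

    LET_t = Σ φ_i S_i  / Σ φ_i          (track / fluence average)
    LET_d = Σ φ_i S_i² / Σ φ_i S_i      (dose average)

By the Cauchy-Schwarz inequality LET_d ≥ LET_t always. The dose average
weights each particle by the dose it deposits, which is why it is the
radiobiology quantity of choice: slow, high-LET particles count in
proportion to their damage.

A simplified primaries-only transport (CSDA residual energy plus a
Gaussian energy-spread kernel) produces the canonical monotonically
rising LET-depth curve for a monoenergetic proton beam; secondary-particle
components (the low-energy, high-LET debris of nuclear interactions) are
user-injected spectra, not computed — the machinery shows their effect on
the averages, not their nuclear-physics origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import physics
from .physics import WATER

__all__ = [
    "Species",
    "PROTON",
    "FluenceSpectrum",
    "LETCurve",
    "let_of",
    "average_let",
    "primaries_let_depth_curve",
    "inject_secondary_component",
    "write_spectrum",
    "read_spectrum",
]


@dataclass(frozen=True)
class Species:
    """A charged-particle species: name, charge number z, mass number A."""

    name: str
    charge: int
    mass_number: int

    def __post_init__(self) -> None:
        if self.charge < 1 or self.mass_number < 1:
            raise ValueError("charge and mass number must be ≥ 1")


PROTON = Species("proton", 1, 1)


def _effective_charge(species: Species, beta: float) -> float:
    """Barkas effective charge z_eff = z(1 − exp(−125 β z^(−2/3)))."""
    z = species.charge
    return z * (1.0 - np.exp(-125.0 * beta * z ** (-2.0 / 3.0)))


def let_of(E, species: Species = PROTON) -> float:
    """Unrestricted LET in water (keV/µm) of *species* at kinetic energy E (MeV).

    Protons delegate directly to the water stopping power. Heavier ions
    use effective-charge scaling of the proton stopping power at the same
    velocity (same energy per nucleon) — a documented approximation, not a
    full ion stopping model.
    """
    if not isinstance(species, Species):
        raise TypeError(f"unknown species {species!r}")
    if species == PROTON:
        return physics.stopping_power_kev_um(E, WATER)
    e_per_nucleon = np.asarray(E, dtype=float) / species.mass_number
    gamma = 1.0 + e_per_nucleon / physics.PROTON_MASS_MEV
    beta = np.sqrt(1.0 - 1.0 / gamma**2)
    zeff = _effective_charge(species, beta)
    s_p = physics.stopping_power_kev_um(e_per_nucleon, WATER)
    out = np.asarray(s_p) * zeff**2
    return out if out.ndim else float(out)


@dataclass
class FluenceSpectrum:
    """Per-depth, per-species energy-binned fluence.

    ``counts`` has shape (n_depth, n_species, n_energy_bins) in particles
    per unit area (arbitrary units); ``energy_bin_edges`` (MeV) are
    strictly increasing and bin-centre evaluation of S is used throughout.
    """

    depth_bins_mm: np.ndarray
    species: list[Species]
    counts: np.ndarray
    energy_bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.depth_bins_mm = np.asarray(self.depth_bins_mm, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.energy_bin_edges = np.asarray(self.energy_bin_edges, dtype=float)
        if np.any(np.diff(self.energy_bin_edges) <= 0):
            raise ValueError("energy bin edges must be strictly increasing")
        expected = (self.depth_bins_mm.size, len(self.species),
                    self.energy_bin_edges.size - 1)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} != (depth, species, ebin) "
                f"{expected}"
            )
        if np.any(self.counts < 0):
            raise ValueError("fluence counts must be non-negative")

    @property
    def energy_bin_centers(self) -> np.ndarray:
        return 0.5 * (self.energy_bin_edges[1:] + self.energy_bin_edges[:-1])

    def depth_index(self, depth_mm: float) -> int:
        d = self.depth_bins_mm
        tol = 0.5 * float(np.median(np.diff(d))) if d.size > 1 else 1e-6
        if depth_mm < d[0] - tol or depth_mm > d[-1] + tol:
            raise ValueError(f"depth {depth_mm:g} mm outside the binned span")
        return int(np.argmin(np.abs(d - depth_mm)))


@dataclass
class LETCurve:
    """Averaged-LET depth distributions (keV/µm)."""

    depth_mm: np.ndarray
    let_track: np.ndarray
    let_dose: np.ndarray
    components: dict | None = None


def average_let(spectrum: FluenceSpectrum, depth_mm: float) -> tuple[float, float]:
    """(track-averaged, dose-averaged) LET at *depth_mm*.

    Sums run over all species and energy bins with S evaluated at bin
    centres. Raises for zero total fluence at the requested depth.
    """
    i = spectrum.depth_index(depth_mm)
    phi = spectrum.counts[i]  # (species, ebin)
    if phi.sum() <= 0:
        raise ValueError(f"zero total fluence at depth {depth_mm:g} mm: "
                         "averages are undefined")
    centers = spectrum.energy_bin_centers
    S = np.vstack([
        np.atleast_1d(let_of(centers, sp)) for sp in spectrum.species
    ])
    num_t = float(np.sum(phi * S))
    den_t = float(np.sum(phi))
    num_d = float(np.sum(phi * S * S))
    let_track = num_t / den_t
    let_dose = num_d / num_t
    return let_track, let_dose


def primaries_let_depth_curve(
    E0: float,
    grid_step: float = 0.1,
    sigma_E: float = 0.3,
    n_kernel: int = 33,
) -> LETCurve:
    """Averaged-LET depth curve for a primaries-only monoenergetic beam.

    Transports the beam by CSDA: at depth z the central energy is E(z)
    from range inversion; a Gaussian kernel of width *sigma_E* (MeV,
    default 0.3) spreads the local spectrum. Protons whose kernel energy
    falls below the model floor have ranged out and drop from the local
    fluence. With ``sigma_E = 0`` the curve is exactly
    ``let_of(E(z))`` for both averages.
    """
    R = physics.csda_range_mm(E0, WATER)
    z = np.arange(0.0, R, grid_step)
    if sigma_E > 0:
        u = np.linspace(-4.0, 4.0, n_kernel)
        weights = np.exp(-0.5 * u * u)
        offsets = sigma_E * u
    else:
        weights = np.array([1.0])
        offsets = np.array([0.0])
    res = (R - z) * WATER.density / 10.0
    e_central = physics.energy_at_range(
        np.clip(res, 0.0, None), WATER
    )
    lt = np.full_like(z, np.nan)
    ld = np.full_like(z, np.nan)
    for k, e0 in enumerate(np.atleast_1d(e_central)):
        e = e0 + offsets
        alive = e > physics.E_MIN
        if not np.any(alive):
            continue
        w = weights[alive]
        s = physics.stopping_power_kev_um(e[alive], WATER)
        num_t = np.sum(w * s)
        lt[k] = num_t / np.sum(w)
        ld[k] = np.sum(w * s * s) / num_t
    keep = ~np.isnan(lt)
    return LETCurve(z[keep], lt[keep], ld[keep])


def inject_secondary_component(
    spectrum: FluenceSpectrum,
    species: Species,
    relative_fluence: float,
    energy_distribution,
) -> FluenceSpectrum:
    """Return a new spectrum with an added particle component.

    *energy_distribution* gives per-energy-bin weights (length = number of
    energy bins) and is normalized internally; at each depth the new
    component carries ``relative_fluence`` × (existing total fluence at
    that depth). The input spectrum is left untouched. A zero relative
    fluence returns an identical copy.
    """
    if relative_fluence < 0:
        raise ValueError("relative fluence must be non-negative")
    dist = np.asarray(energy_distribution, dtype=float)
    n_e = spectrum.energy_bin_edges.size - 1
    if dist.shape != (n_e,):
        raise ValueError(
            f"energy distribution must have one weight per energy bin "
            f"({n_e}), got shape {dist.shape}"
        )
    if np.any(dist < 0) or dist.sum() <= 0:
        raise ValueError("energy distribution must be non-negative with mass")
    dist = dist / dist.sum()
    species_list = list(spectrum.species)
    if species in species_list:
        s_idx = species_list.index(species)
        counts = spectrum.counts.copy()
    else:
        s_idx = len(species_list)
        species_list = species_list + [species]
        counts = np.concatenate(
            [spectrum.counts,
             np.zeros((spectrum.depth_bins_mm.size, 1, n_e))], axis=1
        )
    totals = spectrum.counts.sum(axis=(1, 2))  # per depth
    counts[:, s_idx, :] += relative_fluence * totals[:, None] * dist[None, :]
    return FluenceSpectrum(spectrum.depth_bins_mm.copy(), species_list,
                           counts, spectrum.energy_bin_edges.copy())


def write_spectrum(path, spectrum: FluenceSpectrum) -> None:
    """Write a fluence spectrum as matrix text.

    Header lines carry species (name,charge,mass) and energy bin edges;
    each body row is one (depth, species) pair: depth_mm species_index
    then the per-bin fluences.
    """
    with open(path, "w") as fh:
        fh.write("# fluence spectrum\n")
        for sp in spectrum.species:
            fh.write(f"# species: {sp.name} {sp.charge} {sp.mass_number}\n")
        edges = " ".join(repr(float(v)) for v in spectrum.energy_bin_edges)
        fh.write(f"# energy_edges_MeV: {edges}\n")
        for i, depth in enumerate(spectrum.depth_bins_mm):
            for j in range(len(spectrum.species)):
                row = " ".join(repr(float(v)) for v in spectrum.counts[i, j])
                fh.write(f"{float(depth)!r} {j} {row}\n")


def read_spectrum(path) -> FluenceSpectrum:
    """Read a fluence spectrum written by :func:`write_spectrum`."""
    species = []
    edges = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("species:"):
                    parts = body.split(":", 1)[1].split()
                    species.append(Species(parts[0], int(parts[1]), int(parts[2])))
                elif body.startswith("energy_edges_MeV:"):
                    edges = np.array(
                        [float(v) for v in body.split(":", 1)[1].split()]
                    )
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed spectrum row")
            rows.append((float(parts[0]), int(parts[1]),
                         np.array([float(v) for v in parts[2:]])))
    if edges is None or not species or not rows:
        raise ValueError(f"{path}: incomplete spectrum file")
    depths = sorted({r[0] for r in rows})
    depth_idx = {d: i for i, d in enumerate(depths)}
    counts = np.zeros((len(depths), len(species), edges.size - 1))
    for depth, j, fluences in rows:
        counts[depth_idx[depth], j, :] = fluences
    return FluenceSpectrum(np.array(depths), species, counts, edges)
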