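"""Absolute dosimetry bookkeeping for passive proton beams.

Implements the TRS-398 chain for a calibrated ionization chamber,

    D_w,Q = M_Q · N_D,w,Q0 · k_Q,Q0 ,

where M_Q is the influence-corrected chamber reading, N_D,w,Q0 the
absorbed-dose-to-water calibration factor at the reference quality
(usually Co-60) and k_Q,Q0 the chamber-specific beam-quality correction,
interpolated on the residual range R_res (the proton beam-quality index).
Alongside: monitor-unit calibration (cGy/MU at mid-SOBP), output-factor
normalization to the reference collimator, and the pulsed-beam average
dose-rate arithmetic used for laser-driven source bookkeeping.

k_Q tables are user-supplied; any bundled example table is illustrative,
not clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChamberCalibration",
    "ChamberReading",
    "OutputFactorSet",
    "absorbed_dose",
    "monitor_calibration",
    "normalize_output_factors",
    "average_dose_rate",
    "read_chamber_file",
    "write_chamber_file",
]

#: reference collimator area in mm² (25 mm diameter circular field)
REFERENCE_COLLIMATOR_AREA = 490.0

#: default allowed output-factor drop from the reference field
DEFAULT_OF_DROP_BOUND = 0.03


@dataclass
class ChamberCalibration:
    """Ionization-chamber calibration data.

    ``N_DwQ0`` is in Gy per reading unit; ``kQ_table`` is a list of
    (R_res mm, k_Q) pairs with strictly increasing R_res and k_Q within
    [0.9, 1.1].
    """

    chamber_name: str
    N_DwQ0: float
    kQ_table: list[tuple[float, float]]
    reference_quality: str = "Co-60"

    def __post_init__(self) -> None:
        if self.N_DwQ0 <= 0:
            raise ValueError("N_D,w,Q0 must be positive")
        if not self.kQ_table:
            raise ValueError("kQ table must not be empty")
        arr = np.asarray(self.kQ_table, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("kQ table must be (Rres, kQ) pairs")
        if arr.shape[0] > 1 and np.any(np.diff(arr[:, 0]) <= 0):
            raise ValueError("kQ table Rres values must be strictly increasing")
        if np.any(arr[:, 1] < 0.9) or np.any(arr[:, 1] > 1.1):
            raise ValueError("kQ values must lie within [0.9, 1.1]")
        self._rres = arr[:, 0]
        self._kq = arr[:, 1]

    def kQ(self, Rres: float) -> float:
        """k_Q at *Rres*, linearly interpolated; refuses extrapolation."""
        if Rres < self._rres[0] or Rres > self._rres[-1]:
            raise ValueError(
                f"Rres = {Rres:g} mm outside the kQ table span "
                f"[{self._rres[0]:g}, {self._rres[-1]:g}] mm; "
                "extrapolation is refused"
            )
        return float(np.interp(Rres, self._rres, self._kq))


@dataclass
class ChamberReading:
    """Chamber reading with labeled multiplicative influence corrections.

    Corrections (temperature-pressure, polarity, recombination, ...) are a
    mapping label → factor, applied multiplicatively to ``M_Q``.
    """

    M_Q: float
    influence_corrections: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.M_Q <= 0:
            raise ValueError("chamber reading must be positive")
        for label, f in self.influence_corrections.items():
            if f <= 0:
                raise ValueError(f"influence correction {label!r} must be positive")

    @property
    def corrected(self) -> float:
        m = self.M_Q
        for f in self.influence_corrections.values():
            m *= f
        return m


def absorbed_dose(reading: ChamberReading, cal: ChamberCalibration,
                  Rres: float) -> float:
    """Absorbed dose to water in Gy: D = M_Q · Πcorrections · N_D,w,Q0 · k_Q(R_res)."""
    return reading.corrected * cal.N_DwQ0 * cal.kQ(Rres)


def monitor_calibration(D_gy: float, monitor_units: float) -> float:
    """Monitor calibration in cGy/MU from a mid-SOBP dose measurement."""
    if monitor_units <= 0:
        raise ValueError("monitor units must be positive")
    return 100.0 * D_gy / monitor_units


@dataclass
class OutputFactorSet:
    """Output factors per collimator area, normalized to the reference field."""

    entries: list[tuple[float, float]]  # (area mm², OF)
    reference_area: float = REFERENCE_COLLIMATOR_AREA
    flagged: list[tuple[float, float]] = field(default_factory=list)

    def of_at(self, area: float) -> float:
        for a, of in self.entries:
            if a == area:
                return of
        raise KeyError(f"no output factor for area {area:g} mm²")


def normalize_output_factors(
    entries,
    reference_area: float = REFERENCE_COLLIMATOR_AREA,
    drop_bound: float = DEFAULT_OF_DROP_BOUND,
) -> OutputFactorSet:
    """Normalize output factors to the reference collimator.

    Divides every OF by the reference entry (idempotent) and flags entries
    whose normalized OF drops more than *drop_bound* below 1 — passive
    eye-therapy lines are expected to lose less than 3% of output down to
    the smallest clinical collimator.
    """
    entries = [(float(a), float(of)) for a, of in entries]
    ref = [of for a, of in entries if a == reference_area]
    if not ref:
        raise ValueError(
            f"reference collimator area {reference_area:g} mm² not among entries"
        )
    ref_of = ref[0]
    if ref_of <= 0:
        raise ValueError("reference output factor must be positive")
    normalized = [(a, of / ref_of) for a, of in entries]
    flagged = [(a, of) for a, of in normalized if of < 1.0 - drop_bound]
    return OutputFactorSet(normalized, reference_area, flagged)


def average_dose_rate(dose_per_pulse_gy: float, repetition_rate_hz: float) -> float:
    """Average dose rate in Gy/min of a pulsed beam: D/pulse × rate × 60."""
    if dose_per_pulse_gy < 0 or repetition_rate_hz < 0:
        raise ValueError("dose per pulse and repetition rate must be non-negative")
    return dose_per_pulse_gy * repetition_rate_hz * 60.0


def write_chamber_file(path, cal: ChamberCalibration) -> None:
    """Write a chamber calibration file: # header then (Rres mm, kQ) rows."""
    with open(path, "w") as fh:
        fh.write(f"# chamber: {cal.chamber_name}\n")
        fh.write(f"# N_DwQ0: {cal.N_DwQ0!r}\n")
        fh.write(f"# reference_quality: {cal.reference_quality}\n")
        fh.write("# columns: Rres_mm kQ\n")
        for r, k in cal.kQ_table:
            fh.write(f"{float(r)!r} {float(k)!r}\n")


def read_chamber_file(path) -> ChamberCalibration:
    """Read a chamber calibration file written by :func:`write_chamber_file`."""
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
                raise ValueError(f"{path}:{lineno}: expected 'Rres kQ'")
            rows.append((float(parts[0]), float(parts[1])))
    if "N_DwQ0" not in meta:
        raise ValueError(f"{path}: missing N_DwQ0 header")
    return ChamberCalibration(
        chamber_name=meta.get("chamber", "unknown"),
        N_DwQ0=float(meta["N_DwQ0"]),
        kQ_table=rows,
        reference_quality=meta.get("reference_quality", "Co-60"),
    )
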