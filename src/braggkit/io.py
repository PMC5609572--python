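"""Scan-file and configuration I/O.

Depth-dose and lateral-profile scans travel as two-column text (position
mm, dose a.u.) with optional ``# key: value`` header lines; run
configurations are YAML with fixed units (mm, MeV, Gy) — no unit
auto-detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["ScanCurve", "RunConfig", "read_scan", "write_scan",
           "read_config"]


@dataclass
class ScanCurve:
    """A 1-D scan: strictly increasing positions, doses, header metadata."""

    position_mm: np.ndarray
    dose: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.position_mm.shape != self.dose.shape:
            raise ValueError("position and dose columns differ in length")
        if np.any(np.diff(self.position_mm) <= 0):
            raise ValueError("position column must be strictly increasing")


def write_scan(path, position_mm, dose, metadata: dict | None = None) -> None:
    """Write a two-column scan file; metadata becomes # header lines.

    Values are written with repr so a read-back is bit-identical.
    """
    position_mm = np.asarray(position_mm, dtype=float)
    dose = np.asarray(dose, dtype=float)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        for p, d in zip(position_mm, dose):
            fh.write(f"{float(p)!r} {float(d)!r}\n")


def read_scan(path) -> ScanCurve:
    """Read a two-column scan file; malformed rows raise with line numbers."""
    meta = {}
    pos, dose = [], []
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
            try:
                pos.append(float(parts[0]))
                dose.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
    if not pos:
        raise ValueError(f"{path}: no data rows")
    return ScanCurve(np.array(pos), np.array(dose), meta)


@dataclass
class RunConfig:
    """Run configuration: beam, grid, seeds and per-command options."""

    beam_energy: float = 62.0
    grid_step: float = 0.05
    seed: int = 0
    straggling_factor: float = 0.012
    options: dict = field(default_factory=dict)


def read_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys land in ``options``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: raw.pop(k) for k in
             ("beam_energy", "grid_step", "seed", "straggling_factor")
             if k in raw}
    return RunConfig(**known, options=raw)
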