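"""Radiochromic film dosimetry: netOD, cubic calibration, 2D dose maps.

EBT3-style film darkens with dose; scanned in transmission, the red
channel intensity I relates to dose through the net optical density

    netOD = log10(I_unexposed / I_exposed),

and dose is mapped from netOD by a third-order polynomial fitted over the
calibration exposures (0.25-4 Gy for low-energy proton work). The cubic
runs netOD → dose directly, so converting a scan is polynomial evaluation,
never root finding. A seeded synthetic-film generator (inverse mapping
plus digitization noise) closes the loop for testing without a scanner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilmScan",
    "CalibrationCurve",
    "DoseMap",
    "net_od",
    "fit_calibration",
    "dose_map",
    "synthetic_scan",
    "read_scan_file",
    "write_dose_map",
    "DEFAULT_DOSE_RANGE",
]

#: calibration exposure window in Gy
DEFAULT_DOSE_RANGE = (0.25, 4.0)


@dataclass
class FilmScan:
    """A digitized film: 16-bit red-channel intensities plus scan geometry."""

    pixel_matrix: np.ndarray
    dpi: float
    background_value: float

    def __post_init__(self) -> None:
        self.pixel_matrix = np.asarray(self.pixel_matrix)
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.background_value <= 0:
            raise ValueError("background (unexposed) intensity must be positive")
        if np.any(self.pixel_matrix < 1) or np.any(self.pixel_matrix > 65535):
            raise ValueError("pixel intensities must lie in [1, 65535]")

    @property
    def pixel_pitch_mm(self) -> float:
        return 25.4 / self.dpi


@dataclass
class CalibrationCurve:
    """Dose (Gy) as a cubic in netOD, with fit diagnostics.

    ``coefficients`` are (c0, c1, c2, c3) in dose = c0 + c1·x + c2·x² + c3·x³;
    the curve is strictly increasing over the fitted netOD span.
    """

    coefficients: np.ndarray
    valid_dose_range: tuple[float, float] = DEFAULT_DOSE_RANGE
    fit_residual_rms: float = 0.0
    netod_span: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (4,):
            raise ValueError("expected 4 cubic coefficients (c0..c3)")

    def dose(self, netod):
        x = np.asarray(netod, dtype=float)
        c0, c1, c2, c3 = self.coefficients
        out = c0 + x * (c1 + x * (c2 + x * c3))
        return out if out.ndim else float(out)

    def netod(self, dose_gy: float) -> float:
        """Inverse map for synthesis: smallest real root in the fitted span."""
        c0, c1, c2, c3 = self.coefficients
        roots = np.roots([c3, c2, c1, c0 - dose_gy])
        real = roots[np.abs(roots.imag) < 1e-9].real
        lo, hi = self.netod_span
        ok = real[(real >= lo - 1e-12) & (real <= hi + 1e-12)]
        if ok.size == 0:
            ok = real[real >= 0]
        if ok.size == 0:
            raise ValueError(f"dose {dose_gy:g} Gy outside the invertible span")
        return float(ok.min())


def net_od(exposed_intensity, unexposed_intensity):
    """netOD = log10(I_unexposed / I_exposed), element-wise.

    Non-negative whenever the exposed film is darker than the unexposed
    reference. Film-base handling is folded into the unexposed reference.
    """
    exposed = np.asarray(exposed_intensity, dtype=float)
    unexposed = np.asarray(unexposed_intensity, dtype=float)
    if np.any(exposed <= 0) or np.any(unexposed <= 0):
        raise ValueError("intensities must be strictly positive")
    out = np.log10(unexposed / exposed)
    return out if out.ndim else float(out)


def fit_calibration(
    net_ods,
    doses_gy,
    constrain_origin: bool = False,
    valid_dose_range: tuple[float, float] = DEFAULT_DOSE_RANGE,
) -> CalibrationCurve:
    """Least-squares cubic dose(netOD) fit over the calibration exposures.

    Requires at least 5 points (4 without the constant term when the
    origin is constrained still leaves one redundant). With
    ``constrain_origin`` the constant term is fixed at 0, so zero netOD
    maps to zero dose exactly. The fitted curve must be strictly
    increasing over the netOD span of the data; otherwise the fit is
    rejected (more points or a lower order are needed).
    """
    x = np.asarray(net_ods, dtype=float)
    y = np.asarray(doses_gy, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("netOD and dose arrays must be 1-D and equal length")
    if x.size < 5:
        raise ValueError("need at least 5 calibration points")
    if constrain_origin:
        A = np.column_stack([x, x**2, x**3])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        coeffs = np.concatenate(([0.0], sol))
    else:
        A = np.column_stack([np.ones_like(x), x, x**2, x**3])
        coeffs, *_ = np.linalg.lstsq(A, y, rcond=None)
    span = (float(x.min()), float(x.max()))
    grid = np.linspace(span[0], span[1], 512)
    _, c1, c2, c3 = coeffs
    deriv = c1 + 2 * c2 * grid + 3 * c3 * grid**2
    if np.any(deriv <= 0):
        raise ValueError(
            "fitted cubic is not strictly increasing over the data span; "
            "add calibration points or lower the polynomial order"
        )
    pred = coeffs[0] + x * (coeffs[1] + x * (coeffs[2] + x * coeffs[3]))
    rms = float(np.sqrt(np.mean((pred - y) ** 2)))
    return CalibrationCurve(coeffs, valid_dose_range, rms, span)


@dataclass
class DoseMap:
    """2D dose map in Gy with mm coordinate axes and out-of-range flags."""

    dose_gy: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    out_of_range: np.ndarray = field(default=None)

    def profile_x(self, y_mm: float = 0.0):
        """Horizontal 1-D profile through the row closest to *y_mm*."""
        i = int(np.argmin(np.abs(self.y_mm - y_mm)))
        return self.x_mm, self.dose_gy[i, :]


def dose_map(scan: FilmScan, curve: CalibrationCurve,
             warn_fraction: float = 0.01) -> DoseMap:
    """Convert a film scan to a 2D dose map through a calibration curve.

    Pixel pitch is 25.4/dpi mm; axes are centred on the scan. Doses
    outside the curve's valid range are flagged per-pixel (never clipped);
    a warning reports the count when more than *warn_fraction* of pixels
    with non-trivial netOD are out of range.
    """
    od = net_od(scan.pixel_matrix, scan.background_value)
    dose = curve.dose(od)
    lo, hi = curve.valid_dose_range
    out = (dose > hi) | (dose < 0)
    infield = od > 0.5 * np.max(od) if np.max(od) > 0 else np.zeros_like(od, bool)
    n_bad = int(np.count_nonzero(out & infield))
    n_field = max(int(np.count_nonzero(infield)), 1)
    if n_bad / n_field > warn_fraction:
        warnings.warn(
            f"{n_bad} in-field pixels map outside the valid dose range "
            f"[{lo:g}, {hi:g}] Gy",
            stacklevel=2,
        )
    ny, nx = dose.shape
    pitch = scan.pixel_pitch_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * pitch
    y = (np.arange(ny) - (ny - 1) / 2.0) * pitch
    return DoseMap(dose, x, y, out)


def synthetic_scan(
    dose_field_gy: np.ndarray,
    curve: CalibrationCurve,
    dpi: float = 254.0,
    background_value: float = 40000.0,
    noise_sigma_fraction: float = 0.002,
    seed: int = 0,
) -> FilmScan:
    """Forward-simulate a film scan from a known dose field (synthetic).

    Inverts the calibration cubic per distinct dose, converts netOD to a
    16-bit intensity, and adds seeded Gaussian digitization noise
    (default 0.2% of intensity). The generator is the test-bed inverse of
    :func:`dose_map`.
    """
    dose_field = np.asarray(dose_field_gy, dtype=float)
    values, inverse = np.unique(dose_field, return_inverse=True)
    ods = np.array([0.0 if v <= 0 else curve.netod(v) for v in values])
    od_field = ods[inverse].reshape(dose_field.shape)
    intensity = background_value * 10.0 ** (-od_field)
    if noise_sigma_fraction > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (
            1.0 + noise_sigma_fraction * rng.standard_normal(intensity.shape)
        )
    pixels = np.clip(np.rint(intensity), 1, 65535).astype(np.uint16)
    return FilmScan(pixels, dpi, background_value)


def read_scan_file(path, dpi: float | None = None,
                   background_value: float | None = None) -> FilmScan:
    """Read a film scan from 16-bit TIFF (red channel) or matrix text.

    Text files may carry ``# dpi:`` and ``# background:`` headers; TIFF
    needs them passed explicitly. A missing background defaults to the
    matrix maximum (an unexposed corner is assumed in frame).
    """
    spath = str(path)
    if spath.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(spath)
        if arr.ndim == 3:  # RGB: red channel carries the dosimetric signal
            arr = arr[..., 0]
        if dpi is None:
            raise ValueError("dpi must be given for TIFF scans")
    else:
        meta = {}
        with open(spath) as fh:
            header = []
            for line in fh:
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if ":" in body:
                        k, v = body.split(":", 1)
                        meta[k.strip()] = v.strip()
                else:
                    header.append(line)
        arr = np.loadtxt(spath)
        if dpi is None and "dpi" in meta:
            dpi = float(meta["dpi"])
        if background_value is None and "background" in meta:
            background_value = float(meta["background"])
        if dpi is None:
            raise ValueError("dpi missing: pass it or add a '# dpi:' header")
    if background_value is None:
        background_value = float(np.max(arr))
    return FilmScan(np.atleast_2d(arr), dpi, background_value)


def write_dose_map(path, dmap: DoseMap, dpi: float, curve_id: str = "") -> None:
    """Write a dose map as matrix text with a # header (dpi, curve id)."""
    with open(path, "w") as fh:
        fh.write(f"# dpi: {dpi!r}\n")
        if curve_id:
            fh.write(f"# curve: {curve_id}\n")
        fh.write("# units: Gy\n")
        np.savetxt(fh, dmap.dose_gy, fmt="%.8g")
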