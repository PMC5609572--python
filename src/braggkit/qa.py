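"""Beam QA metrics for depth-dose curves and lateral profiles.

Depth-dose (SOBP) parameters follow clinical passive-beam practice:

* range: depth of the 90% point on the distal falloff,
* SOBP extent: distance between the proximal and distal 95% points,
* reference depth z_ref: midpoint of the 95-95% extent, where curves are
  normalized to 100%,
* beam quality: residual range R_res = R_p − z_ref, with R_p the depth
  where the dose beyond the SOBP falls to 10%,
* longitudinal homogeneity: (Dmax − Dmin)/(Dmax + Dmin) × 100% inside the
  SOBP (a max/min ratio form is available as an alternative).

Lateral-profile parameters: field size (width at 50%), W95 (width between
the outermost 95% crossings), lateral penumbra (mean left/right 80-20%
distance), flatness within W95, and symmetry as the left/right half-field
integral ratio × 100 about the field centre.

All threshold crossings are located by linear interpolation between the
bracketing samples; proximal/plateau-side thresholds take the crossing
nearest the surface, distal/edge thresholds the outermost one, which makes
the extraction robust to percent-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SOBPMetrics",
    "LateralMetrics",
    "BeamQuality",
    "normalize_to_zref",
    "extract_sobp_metrics",
    "extract_lateral_metrics",
    "residual_range",
    "beam_quality",
    "MetricUndefinedError",
    "NoPlateauError",
]


class MetricUndefinedError(RuntimeError):
    """A threshold is never crossed; carries the reason."""


class NoPlateauError(ValueError):
    """Curve has no identifiable plateau (e.g. monotone)."""


@dataclass(frozen=True)
class SOBPMetrics:
    """Depth-dose QA bundle for a modulated beam (all depths in mm)."""

    proximal95: float
    distal95: float
    sobp_width: float
    range90: float
    penumbra_80_20: float
    penumbra_90_10: float
    zref: float
    homogeneity: float  # percent

    def as_dict(self) -> dict:
        return {
            "proximal95_mm": self.proximal95,
            "distal95_mm": self.distal95,
            "sobp_width_mm": self.sobp_width,
            "range90_mm": self.range90,
            "penumbra_80_20_mm": self.penumbra_80_20,
            "penumbra_90_10_mm": self.penumbra_90_10,
            "zref_mm": self.zref,
            "homogeneity_percent": self.homogeneity,
        }


@dataclass(frozen=True)
class LateralMetrics:
    """Lateral-profile QA bundle (positions in mm, ratios in percent)."""

    field_size_w50: float
    w95: float
    lateral_penumbra_80_20: float
    flatness: float  # percent
    symmetry: float  # percent
    axis_label: str = ""

    def as_dict(self) -> dict:
        return {
            "axis": self.axis_label,
            "field_size_w50_mm": self.field_size_w50,
            "w95_mm": self.w95,
            "lateral_penumbra_80_20_mm": self.lateral_penumbra_80_20,
            "flatness_percent": self.flatness,
            "symmetry_percent": self.symmetry,
        }


@dataclass(frozen=True)
class BeamQuality:
    """TRS-398 proton beam-quality index bundle."""

    Rp: float
    zref: float
    Rres: float


def _as_curve(curve):
    """Accept an SOBPCurve-like object or a (depth, dose) pair."""
    if hasattr(curve, "depth_mm") and hasattr(curve, "dose"):
        return np.asarray(curve.depth_mm, float), np.asarray(curve.dose, float)
    z, d = curve
    return np.asarray(z, float), np.asarray(d, float)


def _crossings(z: np.ndarray, d: np.ndarray, level: float) -> np.ndarray:
    """All depths where the curve crosses *level*, linearly interpolated."""
    s = d - level
    hits = []
    exact = np.nonzero(s == 0.0)[0]
    for i in exact:
        hits.append(z[i])
    idx = np.nonzero(s[:-1] * s[1:] < 0.0)[0]
    for i in idx:
        f = s[i] / (s[i] - s[i + 1])
        hits.append(z[i] + f * (z[i + 1] - z[i]))
    if not hits:
        raise MetricUndefinedError(
            f"dose level {level:g} is never crossed"
        )
    return np.unique(hits)


def _proximal_crossing(z, d, level) -> float:
    return float(_crossings(z, d, level)[0])


def _distal_crossing(z, d, level) -> float:
    return float(_crossings(z, d, level)[-1])


def normalize_to_zref(curve):
    """Normalize a depth-dose curve to 100% at the reference depth.

    z_ref is the midpoint of the proximal and distal 95% points, found on
    the provisionally max-normalized curve and refined once after
    renormalizing (the operation is idempotent). Returns
    ``(depth, dose_percent, zref)``. Raises :class:`NoPlateauError` for a
    curve with no plateau (e.g. strictly monotone dose).
    """
    z, d = _as_curve(curve)
    if d.max() <= 0:
        raise NoPlateauError("curve has no positive dose")
    dn = d / d.max() * 100.0
    try:
        c95 = _crossings(z, dn, 95.0)
    except MetricUndefinedError as exc:
        raise NoPlateauError("no 95% plateau found") from exc
    if c95.size < 2:
        raise NoPlateauError(
            "curve crosses 95% only once (monotone curve has no plateau)"
        )
    zref = 0.5 * (c95[0] + c95[-1])
    # refine once: renormalize at zref, recompute the 95% points
    dref = np.interp(zref, z, dn)
    if dref <= 0:
        raise NoPlateauError("zero dose at the candidate reference depth")
    dn = dn / dref * 100.0
    zref = 0.5 * (_proximal_crossing(z, dn, 95.0)
                  + _distal_crossing(z, dn, 95.0))
    dn = dn / np.interp(zref, z, dn) * 100.0
    return z, dn, float(zref)


def extract_sobp_metrics(
    curve,
    homogeneity_mode: str = "difference",
    homogeneity_margin: float | None = None,
) -> SOBPMetrics:
    """Extract the depth-dose QA bundle from a modulated curve.

    The curve is normalized to 100% at z_ref first (idempotent, so
    pre-normalized input is fine); all levels are percentages of the
    plateau. ``homogeneity_mode`` selects ``"difference"``
    ((Dmax−Dmin)/(Dmax+Dmin)×100) or ``"ratio"`` (100×Dmax/Dmin).

    Homogeneity measures plateau ripple over the 95-95% extent shrunk on
    each side by ``homogeneity_margin`` mm (default: the distal 80-20%
    penumbra width). The margin excludes the shoulder samples that by
    construction pass from 95% up to the plateau — with a zero margin the
    metric has a floor of (100−95)/(100+95) ≈ 2.6% on any continuously
    sampled curve, regardless of how flat the plateau is. Pass
    ``homogeneity_margin=0`` for the literal closed-interval evaluation.
    """
    z, dn, zref = normalize_to_zref(curve)
    proximal95 = _proximal_crossing(z, dn, 95.0)
    distal95 = _distal_crossing(z, dn, 95.0)
    range90 = _distal_crossing(z, dn, 90.0)
    z80 = _distal_crossing(z, dn, 80.0)
    z20 = _distal_crossing(z, dn, 20.0)
    z90 = _distal_crossing(z, dn, 90.0)
    z10 = _distal_crossing(z, dn, 10.0)
    if homogeneity_margin is None:
        homogeneity_margin = z20 - z80
    lo = proximal95 + homogeneity_margin
    hi = distal95 - homogeneity_margin
    if hi <= lo:
        lo, hi = proximal95, distal95  # degenerate SOBP: fall back to full extent
    plateau = dn[(z >= lo) & (z <= hi)]
    dmax, dmin = plateau.max(), plateau.min()
    if homogeneity_mode == "difference":
        homogeneity = (dmax - dmin) / (dmax + dmin) * 100.0
    elif homogeneity_mode == "ratio":
        homogeneity = 100.0 * dmax / dmin
    else:
        raise ValueError(f"unknown homogeneity mode {homogeneity_mode!r}")
    return SOBPMetrics(
        proximal95=proximal95,
        distal95=distal95,
        sobp_width=distal95 - proximal95,
        range90=range90,
        penumbra_80_20=z20 - z80,
        penumbra_90_10=z10 - z90,
        zref=zref,
        homogeneity=homogeneity,
    )


def residual_range(Rp: float, zref: float) -> float:
    """Residual range R_res = R_p − z_ref (mm); requires Rp > zref."""
    if Rp <= zref:
        raise ValueError("Rp must exceed zref for a clinical beam")
    return Rp - zref


def beam_quality(curve) -> BeamQuality:
    """Beam-quality bundle: R_p (distal 10% depth), z_ref and R_res."""
    z, dn, zref = normalize_to_zref(curve)
    Rp = _distal_crossing(z, dn, 10.0)
    return BeamQuality(Rp=Rp, zref=zref, Rres=residual_range(Rp, zref))


def extract_lateral_metrics(profile, axis_label: str = "") -> LateralMetrics:
    """Extract the lateral QA bundle from a transverse profile.

    *profile* is ``(positions mm, dose)``; the dose is normalized to 100%
    at the central axis (x = 0, interpolated), so pre-normalized input is
    unchanged. Requires two 50% crossings (a proper field edge on both
    sides). Symmetry integrates the two half-fields about the field centre
    (midpoint of the 50% crossings) and reports 100 × left/right.
    """
    x, d = profile
    x = np.asarray(x, float)
    d = np.asarray(d, float)
    axis_dose = np.interp(0.0, x, d)
    if axis_dose <= 0:
        raise ValueError("non-positive dose on the central axis")
    dn = d / axis_dose * 100.0
    c50 = _crossings(x, dn, 50.0)
    if c50.size < 2:
        raise MetricUndefinedError("fewer than two 50% crossings")
    left50, right50 = float(c50[0]), float(c50[-1])
    field_size = right50 - left50
    c95 = _crossings(x, dn, 95.0)
    w95_left, w95_right = float(c95[0]), float(c95[-1])
    w95 = w95_right - w95_left
    c80 = _crossings(x, dn, 80.0)
    c20 = _crossings(x, dn, 20.0)
    pen_left = c80[0] - c20[0]
    pen_right = c20[-1] - c80[-1]
    penumbra = 0.5 * (pen_left + pen_right)
    infield = dn[(x >= w95_left) & (x <= w95_right)]
    flatness = (infield.max() - infield.min()) / (infield.max() + infield.min()) * 100.0
    centre = 0.5 * (left50 + right50)
    dose_c = np.interp(centre, x, dn)
    lm = x <= centre
    xl = np.append(x[lm], centre)
    dl = np.append(dn[lm], dose_c)
    rm = x >= centre
    xr = np.insert(x[rm], 0, centre)
    dr = np.insert(dn[rm], 0, dose_c)
    left_int = np.trapezoid(dl, xl)
    right_int = np.trapezoid(dr, xr)
    if right_int <= 0:
        raise MetricUndefinedError("right half-field integral is non-positive")
    symmetry = 100.0 * left_int / right_int
    return LateralMetrics(
        field_size_w50=field_size,
        w95=w95,
        lateral_penumbra_80_20=float(penumbra),
        flatness=float(flatness),
        symmetry=float(symmetry),
        axis_label=axis_label,
    )
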