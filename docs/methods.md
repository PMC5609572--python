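# Methods

This note records the models braggkit implements, the defaults it ships,
and the reasoning behind the choices that were genuinely open. Nothing
here states a number the test suite or `scripts/acceptance.py` does not
itself compute.

## Stopping power and range (physics)

The electronic mass stopping power of protons uses the relativistic Bethe
formula without shell or density corrections,

    S(E)/ρ = K (Z/A) β⁻² [ ln(2 mₑc² β²γ² / I) − β² ],   K = 0.307075 MeV·cm²/mol,

which is adequate to a few percent for protons of 1–250 MeV in low-Z
media — the regime every operation in this package lives in. Defaults:
water ρ = 1.0 g/cm³, I = 75 eV (the ICRU-standard value), Z/A = 0.5551;
Kapton ρ = 1.42, I = 79.6 eV; tantalum ρ = 16.654, I = 718 eV. Any
published table can replace the closed form via `mode="table"`, which
interpolates log S against log E.

The CSDA range R(E) = ∫ dE′/S(E′) is a cumulative trapezoid on a
log-spaced grid of 4000 points over 0.1–300 MeV, integrated from the
0.1 MeV support floor (the neglected sub-0.1 MeV tail is a few µm of
water). Sharing one grid between `csda_range` and `energy_at_range` makes
the two functions exact piecewise-linear inverses of each other, so
range–energy round trips are bit-stable — a property the slab-degradation
and Bragg-curve code leans on heavily. Slab traversal subtracts each
slab's areal density from the proton's residual range in that material;
a proton whose residual range runs out inside a slab raises an error
naming the material.

Units are fixed throughout: energies MeV, depths mm, slab thicknesses µm,
mass stopping power MeV·cm²/g, linear stopping power keV/µm
(keV/µm = MeV·cm²/g × ρ / 10).

## Pristine Bragg curves (beam)

The depth-dose curve of a monoenergetic beam is the CSDA form
D(z) ∝ S(E(z)) — the stopping power at the local residual energy —
convolved with a Gaussian range-straggling kernel of width

    σ = c · R^0.935   (mm, R the CSDA range in mm; c = 0.012 by default),

the standard power-law parameterization of range straggling in water.
For the 62 MeV beam this gives σ ≈ 0.31 mm and a distal 80–20% falloff
of ≈ 0.5 mm, matching the sharpness expected of clinical ocular beams.
The curve is normalized to peak = 1 on a uniform grid (default 0.05 mm,
never coarser than 0.1 mm, the scanning resolution of clinical water
phantoms). A range shifter is modelled as CSDA slowing through a
water-equivalent slab followed by a fresh curve evaluation, so shifting
commutes with slab composition by construction.

What the generator does **not** model: nuclear attenuation of the primary
fluence (real peak-to-entrance ratios are lower than the CSDA form's),
beam energy spread beyond the straggling kernel, multiple-Coulomb-scatter
lateral spreading, and detector volume averaging. Tests that pass on
these curves therefore validate the analysis machinery, not the fidelity
of any specific facility's measured curves.

Lateral profiles are rectangle-convolved-with-Gaussian fields,
D(x) = ½[erf((x+a)/σ√2) − erf((x−a)/σ√2)], with an optional one-sided
scale factor for asymmetry and seeded multiplicative noise. The 80–20%
penumbra of this model is analytically 2 × 0.8416 σ ≈ 1.683 σ, which the
QA extraction must reproduce.

The "about 30 mm" clinical range claim is honoured with a ±10% band: the
published figure is approximate and includes unmodelled contributions
(air path, monitor chambers) between window and phantom.

## SOBP weight design (sobp)

A modulator wheel is an ordered list of (water-equivalent thickness,
weight) steps; the first step may have thickness zero — the air gap —
and carries the unmodulated, deepest component. Synthesis is the linear
superposition D(z) = Σₖ wₖ Dₖ(z) on a common grid.

Flattening is a non-negative least-squares problem: minimize
‖A w − 1‖² over the requested flat region with w ≥ 0, where column k of
A is the k-th range-shifted peak. NNLS is the standard, reproducible
choice when no algorithm is otherwise prescribed; the achieved
homogeneity is reported and an infeasible request raises an error
carrying the achieved value. Weights are returned in relative mode
(summing to 1).

Step spacing default: adjacent peak ranges differ by **0.4 ×** the
pristine-peak FWHM. This was a genuinely open choice. With the sharp
σ ≈ 0.31 mm peaks this generator produces, spacings around 0.8 × FWHM
leave ≈ 5% inter-peak ripple in the plateau that *no* weight vector can
remove (the basis simply has gaps), while 0.4 × FWHM brings the floor
below 0.3%, comfortably inside the 2% homogeneity tolerance the designer
defaults to. The spacing is exposed as a parameter; a 16 mm plateau on
the 62 MeV beam needs ≈ 39 steps at the default spacing, and a short
family asked to cover a too-wide region fails loudly with the achieved
homogeneity rather than silently delivering ripple.

The modulator file dialect is one `thickness_mm weight` pair per line,
`#` comments, and a `mode: absolute|relative` header; relative files
whose weights do not sum to 1 are renormalized with a warning. Writes use
shortest round-trip float repr, so read(write(spec)) is bit-exact.

## QA metric extraction (qa)

All threshold crossings are linear interpolations between bracketing
samples. Proximal/plateau-side levels take the crossing nearest the
surface; distal/edge levels take the outermost crossing — the robust
convention when percent-level noise creates multiple crossings.

Depth-dose curves are first normalized to 100% at the reference depth
z_ref, the midpoint of the proximal and distal 95% crossings (found on a
provisionally max-normalized curve, then refined once; the operation is
idempotent and scale-invariant). The bundle then reports: range (distal
90%), SOBP width (95–95%), distal penumbras (80–20% and 90–10%), and
beam quality R_res = R_p − z_ref with R_p the distal 10% depth.

Longitudinal homogeneity is (Dmax − Dmin)/(Dmax + Dmin) × 100 — the
difference form is consistent with the few-percent values clinical
tables print; a max/min ratio form is available behind a flag. The
evaluation window is the 95–95% extent shrunk on each side by the distal
80–20% penumbra width. The margin matters: the closed 95–95% window
necessarily contains shoulder samples climbing from 95% to the plateau,
which caps the metric from below at (100−95)/(100+95) ≈ 2.6% for *every*
continuously sampled curve — flatter-than-2.6% plateaus would be
unreportable. With the margin the metric measures plateau ripple, which
is what a homogeneity tolerance is about. Passing
`homogeneity_margin=0` restores the literal closed-window evaluation.

Lateral profiles are normalized to 100% on the central axis. Field size
is the distance between the two 50% crossings; W95 between the outermost
95% crossings; penumbra is the mean of the left and right 80–20%
distances; flatness uses the difference form within W95; symmetry is
100 × (left half-field integral / right half-field integral) about the
field centre (midpoint of the 50% crossings) — a ratio definition, so
mirroring a profile maps symmetry s → 10000/s exactly.

## Absolute dosimetry (dosimetry)

The absorbed dose to water is the TRS-398 product
D = M_Q · N_D,w,Q0 · k_Q(R_res) with M_Q carrying labeled multiplicative
influence corrections (temperature–pressure, polarity, recombination —
their values are the user's, not the package's). k_Q is linearly
interpolated on residual range; outside the table the code **refuses**
rather than extrapolates — a deliberate safety-over-convenience choice
for a quantity that feeds patient dose. Chamber data live in a small
text format (header with N_D,w,Q0, body of R_res/k_Q pairs); no clinical
k_Q values are bundled.

Monitor calibration is 100 × D/MU (cGy/MU at mid-SOBP). Output factors
are normalized to the 490 mm² reference collimator (25 mm diameter) and
entries dropping more than 3% below the reference are flagged — passive
ocular lines are expected to stay within that bound down to ≈ 50 mm²
fields. Pulsed-beam bookkeeping is dose-per-pulse × repetition rate × 60,
e.g. 2 cGy/pulse at 1 Hz → 1.2 Gy/min.

## Film dosimetry (film)

netOD = log₁₀(I_unexposed / I_exposed) with no separate film-base term:
base and scanner response are folded into the unexposed reference. Dose
is a cubic **in netOD** (not the inverse direction), so converting a scan
is polynomial evaluation; the fit is ordinary least squares on the
explicit Vandermonde (the origin-constrained variant drops the constant
column), requires ≥ 5 points, reports the residual RMS, and rejects fits
that are not strictly increasing over the data span. The valid dose
window defaults to 0.25–4 Gy, the standard ocular-proton calibration
range; out-of-window pixels in a converted map are flagged, never
silently clipped. Film response is treated as energy-independent within
the residual-range interval ≈ 6–29 mm (a documented validity domain,
not a computed correction).

The synthetic scan generator inverts the cubic per distinct dose value,
converts netOD to 16-bit intensity and adds seeded Gaussian digitization
noise (default 0.2% of intensity) — it emulates quantization and shot
noise, not scanner lateral-response nonuniformity or darkening kinetics.

## LET analysis (let)

With φᵢ the fluence in energy bin i (summed over species) and Sᵢ the
unrestricted LET at the bin centre,

    LET_track = Σ φᵢ Sᵢ / Σ φᵢ,      LET_dose = Σ φᵢ Sᵢ² / Σ φᵢ Sᵢ.

LET_dose ≥ LET_track always (Cauchy–Schwarz), both are invariant under
uniform fluence rescaling, and bin-centre evaluation converges under bin
refinement. Proton LET delegates to the water stopping power; heavier
ions use Barkas effective-charge scaling of the proton stopping power at
the same velocity, zeff = z(1 − e^(−125 β z^(−2/3))) — an approximation
good enough for the averaging machinery, not a full ion stopping model.

The primaries-only depth curve transports a monoenergetic beam by CSDA
(central energy from range inversion) and spreads it with a Gaussian
energy kernel (σ_E = 0.3 MeV default, 33 nodes over ±4σ); kernel
components below the 0.1 MeV floor are treated as stopped and drop from
the local fluence. With σ_E = 0 the curve collapses to LET(E(z)) exactly.

Secondary particles are **injected, not computed**: nuclear interaction
products require Monte Carlo transport that is out of scope here. The
injection API adds a user-specified species with a per-bin energy
distribution and a fluence relative to the local total, and the tests
verify the qualitative consequence — added low-energy/high-LET mass
never lowers the dose-averaged LET.

## Problem sizes and determinism

Default problem sizes keep every operation interactive on one CPU: 0.05 mm
depth grids (≈ 700 points for the 62 MeV beam), 4000-point energy grids,
≤ 40-peak SOBP design matrices, film fields of ≈ 10⁵ pixels. The full
test suite runs in seconds. All randomness (profile noise, film noise)
flows through explicit integer seeds recorded in outputs; CLI runs embed
the tool version, seed and a parameter hash so artifacts are reproducible
byte for byte.

## Known limitations

* No nuclear physics anywhere: fluence attenuation, secondary production
  and the resulting entrance-LET enhancement are outside the model.
* Lateral and depth dimensions are independent — no 3D dose engine.
* The Bethe form degrades below ~1 MeV (no shell corrections); the range
  integral's 0.1 MeV floor truncates the last few µm of track.
* QA extraction assumes reasonably clean curves; it tolerates
  percent-level noise via its crossing conventions but is not a fitting
  engine for heavily corrupted scans.
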