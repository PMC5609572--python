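"""Track- and dose-averaged LET machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braggkit import physics
from braggkit.let import (
    PROTON,
    FluenceSpectrum,
    Species,
    average_let,
    inject_secondary_component,
    let_of,
    primaries_let_depth_curve,
    read_spectrum,
    write_spectrum,
)


def make_spectrum(counts, edges=None, depths=None, species=None):
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, None, :]
    if edges is None:
        edges = np.linspace(10.0, 60.0, counts.shape[2] + 1)
    if depths is None:
        depths = np.arange(counts.shape[0], dtype=float)
    if species is None:
        species = [PROTON] * counts.shape[1]
    return FluenceSpectrum(depths, list(species), counts, np.asarray(edges))


class TestLetOf:
    def test_62mev_proton_about_1_kev_um(self):
        assert let_of(62.0, PROTON) == pytest.approx(1.0, rel=0.15)

    def test_decreasing_over_therapeutic_energies(self):
        e = np.linspace(30.0, 200.0, 50)
        vals = np.array([let_of(x, PROTON) for x in e])
        assert np.all(np.diff(vals) < 0)

    def test_proton_delegates_to_stopping_power(self):
        assert let_of(42.0, PROTON) == pytest.approx(
            physics.stopping_power_kev_um(42.0), rel=1e-12)

    def test_alpha_let_exceeds_proton_at_same_velocity(self):
        alpha = Species("alpha", 2, 4)
        # z² scaling at the same energy per nucleon
        assert let_of(4 * 20.0, alpha) > 3.5 * let_of(20.0, PROTON)

    def test_unknown_species_rejected(self):
        with pytest.raises(TypeError):
            let_of(10.0, "carbon")


class TestAverageLet:
    def test_single_bin_degenerate(self):
        spec = make_spectrum([1.0], edges=[59.0, 61.0])
        lt, ld = average_let(spec, 0.0)
        s = let_of(60.0, PROTON)
        assert lt == pytest.approx(s) and ld == pytest.approx(s)

    def test_two_bin_hand_arithmetic(self):
        # φ = (1, 1), S = (1, 3) → track 2.0, dose 2.5
        spec = make_spectrum([1.0, 1.0], edges=[0.0, 2.0, 4.0])
        centers = spec.energy_bin_centers
        s = np.array([let_of(c, PROTON) for c in centers])
        lt, ld = average_let(spec, 0.0)
        assert lt == pytest.approx(s.mean())
        assert ld == pytest.approx((s**2).sum() / s.sum())
        # and the formulas themselves on the stated toy numbers
        phi, svals = np.ones(2), np.array([1.0, 3.0])
        assert (phi * svals).sum() / phi.sum() == pytest.approx(2.0)
        assert (phi * svals**2).sum() / (phi * svals).sum() == pytest.approx(2.5)

    def test_matches_unrolled_brute_force(self):
        rng = np.random.default_rng(9)
        species = [PROTON, Species("deuteron", 1, 2), Species("alpha", 2, 4)]
        counts = rng.random((1, 3, 10))
        spec = make_spectrum(counts, edges=np.linspace(5.0, 55.0, 11),
                             species=species)
        lt, ld = average_let(spec, 0.0)
        num_t = den_t = num_d = 0.0
        for j, sp in enumerate(species):
            for k, c in enumerate(spec.energy_bin_centers):
                s = let_of(c, sp)
                phi = counts[0, j, k]
                num_t += phi * s
                den_t += phi
                num_d += phi * s * s
        assert lt == pytest.approx(num_t / den_t, rel=1e-12)
        assert ld == pytest.approx(num_d / num_t, rel=1e-12)

    def test_zero_fluence_is_undefined_with_reason(self):
        spec = make_spectrum([0.0, 0.0])
        with pytest.raises(ValueError, match="undefined"):
            average_let(spec, 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_dose_average_dominates_track_average(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.random((1, 2, 6)) * rng.integers(1, 100)
        spec = make_spectrum(counts, edges=np.linspace(1.0, 100.0, 7),
                             species=[PROTON, Species("alpha", 2, 4)])
        lt, ld = average_let(spec, 0.0)
        assert ld >= lt - 1e-12

    def test_invariant_under_fluence_rescale(self):
        counts = np.random.default_rng(2).random((1, 1, 8))
        a = average_let(make_spectrum(counts), 0.0)
        b = average_let(make_spectrum(417.0 * counts), 0.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_merging_equals_concatenated_bins(self):
        rng = np.random.default_rng(4)
        c1, c2 = rng.random((1, 1, 5)), rng.random((1, 1, 5))
        edges = np.linspace(10.0, 50.0, 6)
        merged = average_let(make_spectrum(c1 + c2, edges=edges), 0.0)
        both = make_spectrum(
            np.concatenate([c1, c2], axis=1), edges=edges,
            species=[PROTON, PROTON])
        assert average_let(both, 0.0) == pytest.approx(merged, rel=1e-12)


class TestPrimariesCurve:
    def test_entrance_dose_let_about_1_kev_um(self):
        curve = primaries_let_depth_curve(62.0)
        assert curve.let_dose[0] == pytest.approx(1.0, rel=0.15)

    def test_zero_spread_reduces_to_let_of_central_energy(self):
        curve = primaries_let_depth_curve(62.0, grid_step=0.5, sigma_E=0.0)
        R = physics.csda_range_mm(62.0)
        for z, lt in zip(curve.depth_mm[:20], curve.let_track[:20]):
            e = physics.energy_at_range((R - z) / 10.0)
            assert lt == pytest.approx(let_of(e, PROTON), rel=1e-9)
        assert curve.let_track[0] == pytest.approx(let_of(62.0, PROTON),
                                                   rel=1e-6)

    def test_let_rises_toward_range_end(self):
        curve = primaries_let_depth_curve(62.0, grid_step=0.2)
        pre_distal = curve.depth_mm < physics.csda_range_mm(62.0) - 1.0
        assert np.all(np.diff(curve.let_dose[pre_distal]) > 0)


class TestInjection:
    def test_zero_relative_fluence_is_identity(self):
        spec = make_spectrum(np.random.default_rng(6).random((2, 1, 5)))
        out = inject_secondary_component(spec, Species("alpha", 2, 4), 0.0,
                                         np.ones(5))
        np.testing.assert_array_equal(out.counts[:, 0, :], spec.counts[:, 0, :])
        assert np.all(out.counts[:, 1, :] == 0)

    def test_high_let_component_raises_dose_average(self):
        spec = make_spectrum(np.random.default_rng(7).random((3, 1, 6)),
                             edges=np.linspace(20.0, 80.0, 7))
        dist = np.zeros(6)
        dist[0] = 1.0  # lowest-energy (highest-LET) bin
        boosted = inject_secondary_component(
            spec, Species("alpha", 2, 4), 0.3, dist)
        for depth in spec.depth_bins_mm:
            _, ld0 = average_let(spec, depth)
            _, ld1 = average_let(boosted, depth)
            assert ld1 >= ld0

    def test_identical_let_component_keeps_track_average(self):
        spec = make_spectrum([2.0], edges=[59.0, 61.0])
        out = inject_secondary_component(spec, PROTON, 0.5, np.ones(1))
        lt0, _ = average_let(spec, 0.0)
        lt1, _ = average_let(out, 0.0)
        assert lt1 == pytest.approx(lt0, rel=1e-12)

    def test_original_untouched(self):
        spec = make_spectrum([1.0, 2.0])
        before = spec.counts.copy()
        inject_secondary_component(spec, Species("alpha", 2, 4), 1.0,
                                   np.array([1.0, 1.0]))
        np.testing.assert_array_equal(spec.counts, before)

    def test_distribution_must_match_grid(self):
        spec = make_spectrum([1.0, 2.0])
        with pytest.raises(ValueError, match="per energy bin"):
            inject_secondary_component(spec, PROTON, 0.5, np.ones(5))


class TestSpectrumFile:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        spec = make_spectrum(rng.random((3, 2, 4)),
                             species=[PROTON, Species("alpha", 2, 4)],
                             depths=np.array([0.0, 5.0, 10.0]))
        path = tmp_path / "spec.txt"
        write_spectrum(path, spec)
        back = read_spectrum(path)
        np.testing.assert_array_equal(back.counts, spec.counts)
        np.testing.assert_array_equal(back.energy_bin_edges,
                                      spec.energy_bin_edges)
        assert back.species == spec.species
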