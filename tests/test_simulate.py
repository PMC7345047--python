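"""Synthetic spectrum generator: patterns, linearity, determinism, evidence."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrannotate.library import LibraryError, ReferenceSignal
from nmrannotate.simulate import (
    SimulationParams,
    demo_amplitudes,
    simulate_correlations,
    simulate_jres,
    simulate_multiplet,
    simulate_spectrum,
    simulate_spike,
)
from tests.conftest import single_signal_library


def _sig(shift, mult, j=(), **kw):
    return ReferenceSignal(
        "X", "unknown", shift, mult, j_values=tuple(j), confidence_level="2+", **kw
    )


class TestMultipletPatterns:
    def test_triplet_has_binomial_one_two_one(self, params):
        lines = simulate_multiplet(_sig(2.0, "t"), 4.0, params)
        assert len(lines) == 3
        w = [i for _, i in lines]
        assert w[1] / w[0] == pytest.approx(2.0)
        assert w[0] == pytest.approx(w[2])

    def test_glycine_singlet_is_one_line_at_its_shift(self, library, params):
        sig = library.metabolites["Glycine"][0]
        lines = simulate_multiplet(sig, 1.0, params)
        assert len(lines) == 1
        assert lines[0][0] == pytest.approx(3.56)

    def test_doublet_half_splitting_is_j_over_two_freq(self, params):
        # J = 7.2 Hz at 600 MHz: lines at 1.483 +/- 0.0060 ppm
        lines = simulate_multiplet(_sig(1.483, "d", j=(7.2,)), 1.0, params)
        pos = sorted(p for p, _ in lines)
        assert pos[0] == pytest.approx(1.483 - 0.0060, abs=1e-9)
        assert pos[1] == pytest.approx(1.483 + 0.0060, abs=1e-9)

    def test_dd_is_tensor_product_of_doublets(self, params):
        lines = simulate_multiplet(_sig(2.5, "dd", j=(16.0, 6.0)), 1.0, params)
        pos = sorted((p - 2.5) * 600.0 for p, _ in lines)
        assert pos == pytest.approx([-11.0, -5.0, 5.0, 11.0], abs=1e-9)
        assert all(i == pytest.approx(0.25) for _, i in lines)

    def test_unresolved_m_flagged_with_2k_minus_1_lines(self, params):
        lines = simulate_multiplet(_sig(1.8, "m", n_peaks=4), 1.0, params)
        assert len(lines) == 2 * 4 - 1

    @pytest.mark.parametrize("mult,n", [("s", 1), ("d", 2), ("t", 3), ("q", 4)])
    def test_area_independent_of_multiplicity(self, params, mult, n):
        """Binomial weights are normalized: same area whatever the pattern."""
        lines = simulate_multiplet(_sig(2.0, mult), 3.0, params)
        assert len(lines) == n
        assert sum(i for _, i in lines) == pytest.approx(3.0)


class TestSpectrum:
    def test_single_glycine_maximum_at_its_shift(self, library, params):
        sub = single_signal_library(library, "Glycine", 3.56)
        spec, _ = simulate_spectrum(sub, {"Glycine": 1.0}, params)
        away_from_tsp = np.abs(spec.ppm) > 0.3
        apex = spec.ppm[away_from_tsp][np.argmax(spec.intensities[away_from_tsp])]
        assert apex == pytest.approx(3.56, abs=params.grid_step)

    def test_empty_mixture_is_tsp_only(self, library, params):
        spec, truth = simulate_spectrum(library, {}, params)
        assert truth == {}
        # apex may fall between grid points
        assert spec.intensity_at(0.0) == pytest.approx(params.tsp_amplitude, rel=5e-3)
        assert spec.intensity_at(5.0) == pytest.approx(0.0, abs=1e-4)

    def test_same_seed_is_bit_identical(self, library, params):
        amps = {"Alanine": 1.0, "Glycine": 2.0}
        s1, _ = simulate_spectrum(library, amps, params)
        s2, _ = simulate_spectrum(library, amps, params)
        assert np.array_equal(s1.intensities, s2.intensities)

    def test_mixture_is_sum_of_singles_at_zero_noise(self, library, params):
        both, _ = simulate_spectrum(library, {"Glycine": 1.0, "Alanine": 1.0}, params)
        gly, _ = simulate_spectrum(library, {"Glycine": 1.0}, params)
        ala, _ = simulate_spectrum(library, {"Alanine": 1.0}, params)
        tsp, _ = simulate_spectrum(library, {}, params)
        assert np.allclose(
            both.intensities, gly.intensities + ala.intensities - tsp.intensities
        )

    def test_unknown_metabolite_is_named_in_the_error(self, library, params):
        with pytest.raises(LibraryError, match="Caffeine"):
            simulate_spectrum(library, {"Caffeine": 1.0}, params)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(amplitude=st.floats(0.1, 50.0))
    def test_integrated_area_proportional_to_amplitude(self, amplitude):
        params = SimulationParams(rng_seed=3, n_points=16384, spectral_width=10.0,
                                  axis_max=8.0, tsp_amplitude=0.0)
        from nmrannotate.library import ReferenceLibrary

        lib = ReferenceLibrary([_sig(4.0, "t")])
        spec, _ = simulate_spectrum(lib, {"X": amplitude}, params)
        area = -np.trapezoid(spec.intensities, spec.ppm)
        lib1 = ReferenceLibrary([_sig(4.0, "t")])
        ref, _ = simulate_spectrum(lib1, {"X": 1.0}, params)
        unit = -np.trapezoid(ref.intensities, ref.ppm)
        assert area == pytest.approx(amplitude * unit, rel=1e-6)


class TestCorrelations:
    def test_glutamate_tocsy_clique_is_ten_edges(self, library, params):
        corr = simulate_correlations(library, {"Glutamate": 1.0}, params)
        tocsy = [e for e in corr.homonuclear_edges if e[2] == "TOCSY"]
        assert len(tocsy) == 10  # C(5,2) over its five signals

    def test_single_singlet_has_no_homonuclear_edges(self, library, params):
        corr = simulate_correlations(library, {"Trimethylamine": 1.0}, params)
        assert corr.homonuclear_edges == []
        # but carries its 13C correlation at both fields
        assert len(corr.hsqc_pairs) == 2

    def test_full_dropout_empties_the_evidence(self, library):
        params = SimulationParams(rng_seed=1, evidence_dropout=1.0)
        corr = simulate_correlations(library, demo_amplitudes(library), params)
        assert corr.is_empty()

    def test_p31_pairs_only_for_flagged_signals(self, library, params):
        amps = {"M4": 1.0, "Glycine": 1.0}
        corr = simulate_correlations(library, amps, params)
        assert len(corr.p31_pairs) == 1
        sid, shift_p = corr.p31_pairs[0]
        assert library.signals[sid].metabolite_name == "M4"
        assert shift_p == pytest.approx(4.60)


class TestSpike:
    def test_present_metabolite_lines_scale_without_new_positions(self, library, params):
        amps = {"Glycine": 1.0, "Alanine": 1.0}
        spec, truth = simulate_spectrum(library, amps, params)
        post = simulate_spike(spec, truth, library, "Glycine", 5.0, params)
        assert post.intensity_at(3.56) == pytest.approx(5 * spec.intensity_at(3.56), rel=1e-3)
        # alanine untouched (up to the far Lorentzian tail of the added lines)
        assert post.intensity_at(1.483 - 0.00583) == pytest.approx(
            spec.intensity_at(1.483 - 0.00583), rel=1e-4
        )

    def test_absent_metabolite_adds_new_lines_only(self, library, params):
        amps = {"Dimethylamine": 1.0}
        spec, truth = simulate_spectrum(library, amps, params)
        post = simulate_spike(spec, truth, library, "Sarcosine", 5.0, params)
        assert post.intensity_at(2.730) > spec.intensity_at(2.730) + 0.5
        assert post.intensity_at(2.709) == pytest.approx(spec.intensity_at(2.709), rel=1e-2)

    def test_fold_one_on_present_metabolite_is_identity(self, library, params):
        spec, truth = simulate_spectrum(library, {"Glycine": 1.0}, params)
        post = simulate_spike(spec, truth, library, "Glycine", 1.0, params)
        assert np.array_equal(post.intensities, spec.intensities)


def test_jres_table_resolves_coincident_doublets(library, params):
    """Glucose and maltose share 5.237 ppm; the J dimension separates them."""
    amps = {"Glucose": 1.0, "Maltose": 1.0}
    table = simulate_jres(library, amps, params)
    at_5237 = [m for m in table if abs(m.centre - 5.237) < 1e-6]
    assert len(at_5237) == 2
    assert {library.signals[m.signal_id].metabolite_name for m in at_5237} == {
        "Glucose",
        "Maltose",
    }
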