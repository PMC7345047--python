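"""Uniform and intelligent bucketing, metabolite merging, conservation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrannotate.annotate import Annotation, SpinSystem
from nmrannotate.bucketing import (
    Bucket,
    intelligent_buckets,
    merge_buckets,
    uniform_buckets,
)
from nmrannotate.processing import reference_to_tsp
from nmrannotate.simulate import (
    SimulationParams,
    Spectrum1D,
    simulate_jres,
    simulate_spectrum,
)


@pytest.fixture(scope="module")
def glycine_spectrum(library, params):
    spec, _ = simulate_spectrum(library, {"Glycine": 1.0}, params)
    return reference_to_tsp(spec)


class TestUniform:
    def test_ten_ppm_window_at_width_001_gives_thousand_buckets(self, glycine_spectrum):
        buckets = uniform_buckets(
            glycine_spectrum, 0.01, window=(0.0, 10.0), exclusions=()
        )
        assert len(buckets) == 1000

    def test_flat_zero_spectrum_has_zero_intensity(self, params):
        spec = Spectrum1D(params.ppm_axis(), np.zeros(params.n_points), params,
                          referenced=True)
        buckets = uniform_buckets(spec, 0.05, exclusions=())
        assert all(b.intensity == 0.0 for b in buckets)

    def test_bucket_sum_equals_window_integral(self, glycine_spectrum):
        spec = glycine_spectrum
        buckets = uniform_buckets(spec, 0.01, window=(0.5, 10.0), exclusions=())
        mask = (spec.ppm >= 0.5) & (spec.ppm <= 10.0)
        total = -np.trapezoid(spec.intensities[mask], spec.ppm[mask])
        assert sum(b.intensity for b in buckets) == pytest.approx(total, rel=1e-3)

    def test_buckets_ordered_and_non_overlapping(self, glycine_spectrum):
        buckets = uniform_buckets(glycine_spectrum, 0.01)
        for a, b in zip(buckets, buckets[1:]):
            assert a.right >= b.left - 1e-12


class TestIntelligent:
    def test_isolated_singlet_gets_one_bucket_containing_it(self, library, params,
                                                            glycine_spectrum):
        ms = simulate_jres(library, {"Glycine": 1.0}, params)
        buckets = intelligent_buckets(glycine_spectrum, ms)
        assert len(buckets) == 1
        assert buckets[0].right < 3.56 < buckets[0].left

    def test_doublet_spans_one_bucket_not_two(self, library, params):
        spec, _ = simulate_spectrum(library, {"Alanine": 1.0}, params)
        spec = reference_to_tsp(spec)
        ms = [m for m in simulate_jres(library, {"Alanine": 1.0}, params)
              if abs(m.centre - 1.483) < 0.01]
        buckets = intelligent_buckets(spec, ms)
        assert len(buckets) == 1
        up, down = buckets[0].right, buckets[0].left
        assert up < 1.483 - 0.0058 and down > 1.483 + 0.0058

    def test_empty_multiplet_list_gives_no_buckets(self, glycine_spectrum):
        assert intelligent_buckets(glycine_spectrum, []) == []

    def test_overlapping_multiplets_share_a_boundary_with_warning(
        self, library, params
    ):
        amps = {"Leucine": 1.0}
        spec, _ = simulate_spectrum(library, amps, params)
        spec = reference_to_tsp(spec)
        ms = simulate_jres(library, amps, params)  # doublets 0.959/0.972: overlap
        with pytest.warns(UserWarning, match="overlap"):
            buckets = intelligent_buckets(spec, ms)
        assert len(buckets) == 2
        assert buckets[0].right == pytest.approx(buckets[1].left)


class TestMerging:
    def test_valine_multiplet_buckets_merge_into_one_feature(self, library, params):
        amps = {"Valine": 1.0}
        spec, _ = simulate_spectrum(library, amps, params)
        spec = reference_to_tsp(spec)
        ms = simulate_jres(library, amps, params)
        buckets = intelligent_buckets(spec, ms)
        assert len(buckets) == 4
        ann = Annotation(
            system=SpinSystem(1, frozenset(m.signal_id for m in ms)),
            assigned_name="Valine", confidence_level="2+", centre=3.613,
        )
        features, assoc = merge_buckets(buckets, [ann])
        assert list(features["feature"]) == ["Valine"]
        assert features["intensity"].iloc[0] == pytest.approx(
            sum(b.intensity for b in buckets)
        )
        assert set(assoc["metabolite"]) == {"Valine"}

    def test_no_annotations_passes_buckets_through(self):
        buckets = [Bucket(2.0, 1.9, 5.0, signal_id=1), Bucket(1.5, 1.4, 3.0, signal_id=2)]
        features, assoc = merge_buckets(buckets, [])
        assert len(features) == 2
        assert features["intensity"].tolist() == [5.0, 3.0]
        assert (assoc["metabolite"] == "").all()

    def test_merging_conserves_total_intensity(self, full_run):
        from nmrannotate.bucketing import intelligent_buckets as ib

        buckets = ib(full_run.spectrum, full_run.multiplets)
        features, _ = merge_buckets(buckets, full_run.annotations)
        assert features["intensity"].sum() == pytest.approx(
            sum(b.intensity for b in buckets), rel=1e-9
        )
        assert len(features) <= len(buckets)

    def test_fully_annotated_disjoint_mixture_gives_one_feature_per_metabolite(
        self, library, params
    ):
        amps = {"Glycine": 1.0, "Trimethylamine": 1.0, "Succinic acid": 1.0}
        spec, _ = simulate_spectrum(library, amps, params)
        spec = reference_to_tsp(spec)
        ms = simulate_jres(library, amps, params)
        from nmrannotate.simulate import simulate_correlations
        from nmrannotate.annotate import annotate_mixture

        corr = simulate_correlations(library, amps, params)
        anns = annotate_mixture(ms, corr, library)
        buckets = intelligent_buckets(spec, ms)
        features, _ = merge_buckets(buckets, anns)
        assert sorted(features["feature"]) == sorted(amps)


@settings(derandomize=True, max_examples=10, deadline=None)
@given(width=st.floats(0.005, 0.2))
def test_uniform_bucket_count_arithmetic(width):
    params = SimulationParams(rng_seed=0, n_points=8192, spectral_width=12.0,
                              axis_max=11.0)
    spec = Spectrum1D(params.ppm_axis(), np.zeros(8192), params, referenced=True)
    buckets = uniform_buckets(spec, width, window=(0.0, 10.0), exclusions=())
    assert len(buckets) == int(round(10.0 / width))
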