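"""Spin-system assembly, evidence matching, confidence rules, spiking."""

from __future__ import annotations

import dataclasses

import pytest

from nmrannotate.annotate import (
    AnnotationConfig,
    CandidateEvidence,
    EvidenceItem,
    EvidenceLedger,
    annotate_mixture,
    apply_spike_result,
    build_spin_systems,
    decide_confidence,
    evaluate_spike,
    match_library,
    name_unknowns,
)
from nmrannotate.library import ReferenceLibrary, ReferenceSignal
from nmrannotate.processing import Multiplet, Peak
from nmrannotate.simulate import (
    CorrelationSet,
    simulate_correlations,
    simulate_jres,
    simulate_spectrum,
    simulate_spike,
)
from nmrannotate.processing import reference_to_tsp


def _mult(sid, centre, mult="s", count=None, j=None):
    return Multiplet(
        signal_id=sid, centre=centre, multiplicity=mult, n_peaks=count, j_est=j,
        peaks=[Peak(centre, 1.0, 1.3)], area=1.0,
    )


class TestSpinSystems:
    def test_chain_of_edges_is_one_component(self):
        ms = [_mult(1, 2.0), _mult(2, 2.5), _mult(3, 3.0)]
        corr = CorrelationSet(homonuclear_edges=[(1, 2, "COSY"), (2, 3, "COSY")])
        systems = build_spin_systems(ms, corr)
        assert len(systems) == 1
        assert systems[0].member_ids == frozenset({1, 2, 3})

    def test_no_edges_gives_singletons(self):
        ms = [_mult(i, float(i)) for i in range(1, 5)]
        systems = build_spin_systems(ms, CorrelationSet())
        assert len(systems) == 4
        assert all(len(s.member_ids) == 1 for s in systems)

    def test_dangling_endpoint_warns_and_drops_edge(self):
        ms = [_mult(1, 2.0)]
        corr = CorrelationSet(homonuclear_edges=[(1, 99, "COSY")])
        with pytest.warns(UserWarning, match="dangling"):
            systems = build_spin_systems(ms, corr)
        assert len(systems) == 1

    def test_simulated_valine_forms_one_four_member_system(self, library, params):
        amps = {"Valine": 1.0}
        ms = simulate_jres(library, amps, params)
        corr = simulate_correlations(library, amps, params)
        systems = build_spin_systems(ms, corr)
        assert len(systems) == 1
        assert len(systems[0].member_ids) == 4


class TestMatching:
    def test_betaine_singlets_with_c13_pairs_are_fully_coherent(self, library, params):
        amps = {"Betaine": 1.0}
        ms = simulate_jres(library, amps, params)
        corr = simulate_correlations(library, amps, params)
        systems = build_spin_systems(ms, corr)
        # isolated betaine: nothing is crowded, so match both singlets
        config = AnnotationConfig(crowded_regions=())
        coherent_shift = coherent_c13 = contradictions = 0
        for sys_ in systems:
            ledger = match_library(sys_, library, ms, corr, config)
            ev = ledger["Betaine"]
            coherent_shift += sum(1 for i in ev.coherent if i.etype == "h1_shift")
            coherent_c13 += sum(1 for i in ev.coherent if i.etype == "c13_shift")
            contradictions += len(ev.contradictory)
        assert coherent_shift == 2
        assert coherent_c13 == 4  # two signals x two fields
        assert contradictions == 0

    def test_p31_pair_on_a_nonphosphorylated_candidate_contradicts(self, library):
        # a lone singlet at choline's shift that carries a 31P correlation
        ms = [_mult(7, 3.210)]
        corr = CorrelationSet(p31_pairs=[(7, 4.6)])
        systems = build_spin_systems(ms, corr)
        ledger = match_library(systems[0], library, ms, corr)
        ev = ledger["Choline"]
        assert any(
            i.etype == "p31" and i.verdict == "contradictory" for i in ev.items
        )

    def test_system_with_no_candidate_in_tolerance_has_empty_ledger(self, library):
        ms = [_mult(1, 9.95)]
        systems = build_spin_systems(ms, CorrelationSet())
        ledger = match_library(systems[0], library, ms, CorrelationSet())
        assert ledger == {}

    def test_expected_signal_absent_from_spectrum_contradicts(self, library):
        # a lone doublet at UDP's shift: UDP's other doublet is nowhere
        ms = [_mult(1, 5.780, "d", j=7.0)]
        systems = build_spin_systems(ms, CorrelationSet())
        ledger = match_library(systems[0], library, ms, CorrelationSet())
        ev = ledger["UDP"]
        assert any(
            "absent" in i.detail for i in ev.contradictory
        )


def _ledger(name, items):
    ev = CandidateEvidence(metabolite=name, items=items, rms_shift_dev=0.001)
    return EvidenceLedger({name: ev})


class TestConfidence:
    def test_three_coherent_args_with_two_confirmations_is_level_2plus(self):
        ledger = _ledger(
            "X",
            [
                EvidenceItem("h1_shift", "coherent", 1),
                EvidenceItem("c13_shift", "coherent", 1),
                EvidenceItem("homonuclear", "coherent", 1),
            ],
        )
        name, level, _ = decide_confidence(ledger)
        assert (name, level) == ("X", "2+")

    def test_shift_only_match_is_level_2minus(self):
        ledger = _ledger("X", [EvidenceItem("h1_shift", "coherent", 1)])
        assert decide_confidence(ledger)[1] == "2-"

    def test_single_confirmation_is_level_2minus(self):
        ledger = _ledger(
            "X",
            [
                EvidenceItem("h1_shift", "coherent", 1),
                EvidenceItem("multiplicity", "coherent", 1),
                EvidenceItem("c13_shift", "coherent", 1),
            ],
        )
        assert decide_confidence(ledger)[1] == "2-"

    def test_any_contradiction_blocks_assignment(self):
        ledger = _ledger(
            "X",
            [
                EvidenceItem("h1_shift", "coherent", 1),
                EvidenceItem("c13_shift", "coherent", 1),
                EvidenceItem("homonuclear", "coherent", 1),
                EvidenceItem("multiplicity", "contradictory", 1),
            ],
        )
        assert decide_confidence(ledger) == (None, "unassigned", [])

    def test_full_tie_retains_both_and_caps_at_2minus(self):
        items = [
            EvidenceItem("h1_shift", "coherent", 1),
            EvidenceItem("c13_shift", "coherent", 1),
            EvidenceItem("homonuclear", "coherent", 1),
        ]
        ledger = EvidenceLedger(
            {
                "A": CandidateEvidence("A", list(items), rms_shift_dev=0.002),
                "B": CandidateEvidence("B", list(items), rms_shift_dev=0.002),
            }
        )
        name, level, notes = decide_confidence(ledger)
        assert name == "A" and level == "2-"
        assert any("tie" in n for n in notes)

    def test_adding_coherent_evidence_never_lowers_the_level(self):
        order = {"unassigned": 0, "2-": 1, "2+": 2, "1": 3}
        base = [EvidenceItem("h1_shift", "coherent", 1)]
        extras = [
            EvidenceItem("multiplicity", "coherent", 1),
            EvidenceItem("c13_shift", "coherent", 1),
            EvidenceItem("homonuclear", "coherent", 1),
            EvidenceItem("c13_shift", "coherent", 2),
        ]
        prev = order[decide_confidence(_ledger("X", base))[1]]
        for k in range(1, len(extras) + 1):
            level = decide_confidence(_ledger("X", base + extras[:k]))[1]
            assert order[level] >= prev
            prev = order[level]


class TestSpiking:
    def test_glycine_spike_confirms_to_level_1(self, library, params):
        amps = {"Glycine": 1.0, "Alanine": 1.0}
        spec, truth = simulate_spectrum(library, amps, params)
        spec = reference_to_tsp(spec)
        post = simulate_spike(spec, truth, library, "Glycine", 5.0, params)
        ms = simulate_jres(library, amps, params)
        corr = simulate_correlations(library, amps, params)
        anns = annotate_mixture(ms, corr, library)
        gly = next(a for a in anns if a.assigned_name == "Glycine")
        upgraded, outcome = apply_spike_result(
            gly, spec, post, "Glycine", library, ground_truth=truth
        )
        assert outcome.status == "confirmed"
        assert upgraded.confidence_level == "1"

    def test_sarcosine_outcome_rejects_candidate_and_reports_below_detection(
        self, library, params
    ):
        """A decoy singlet matches sarcosine in the database; spiking refutes it."""
        decoy = ReferenceSignal(
            "DecoySinglet", "unknown", 2.740, "s", shift_c13=33.9,
            confidence_level="2-",
        )
        lib = ReferenceLibrary(library.signals + [decoy])
        amps = {"DecoySinglet": 1.0}
        spec, truth = simulate_spectrum(lib, amps, params)
        spec = reference_to_tsp(spec)
        ms = simulate_jres(lib, amps, params)
        corr = simulate_correlations(lib, amps, params)
        systems = build_spin_systems(ms, corr)
        ledger = match_library(systems[0], lib, ms, corr)
        assert "Sarcosine" in ledger  # the database suggests sarcosine
        from nmrannotate.annotate import Annotation

        ann = Annotation(
            system=systems[0], assigned_name="Sarcosine",
            confidence_level="2-", ledger=ledger, centre=2.740,
        )
        post = simulate_spike(spec, truth, lib, "Sarcosine", 5.0, params, present=False)
        rejected, outcome = apply_spike_result(
            ann, spec, post, "Sarcosine", lib, ground_truth=truth
        )
        # new lines appeared, the decoy did not grow: candidate rejected and
        # sarcosine is below the detection level
        assert outcome.status == "undetectable"
        assert outcome.n_new == outcome.n_lines
        assert rejected.assigned_name is None
        assert rejected.confidence_level == "unassigned"
        # the decoy singlet itself is untouched (up to the 6 Hz-away tail of
        # the newly added sarcosine line)
        assert post.intensity_at(2.740) == pytest.approx(
            spec.intensity_at(2.740), rel=2e-2
        )

    def test_udp_spike_yields_only_new_lines_hence_undetectable(self, library, params):
        amps = {"Uridine": 1.0, "UMP": 1.0}
        spec, truth = simulate_spectrum(library, amps, params)
        spec = reference_to_tsp(spec)
        post = simulate_spike(spec, truth, library, "UDP", 5.0, params)
        outcome = evaluate_spike(spec, post, library, "UDP", ground_truth=truth)
        assert outcome.status == "undetectable"
        assert outcome.n_pre_existing == 0

    def test_different_grids_error(self, library, params):
        spec, truth = simulate_spectrum(library, {"Glycine": 1.0}, params)
        spec = reference_to_tsp(spec)
        small = dataclasses.replace(params, n_points=4096)
        other, _ = simulate_spectrum(library, {"Glycine": 1.0}, small)
        with pytest.raises(ValueError, match="different grids"):
            evaluate_spike(spec, other, library, "Glycine", ground_truth=truth)


class TestUnknownNaming:
    def test_sequential_names_in_downfield_order(self):
        from nmrannotate.annotate import Annotation, SpinSystem

        ms = [_mult(1, 2.0), _mult(2, 8.0)]
        anns = [
            Annotation(system=SpinSystem(1, frozenset({1})), centre=2.0),
            Annotation(system=SpinSystem(2, frozenset({2})), centre=8.0),
        ]
        name_unknowns(anns, AnnotationConfig(), ms)
        assert anns[1].assigned_name == "Unknown M1"  # 8.0 ppm is downfield
        assert anns[0].assigned_name == "Unknown M2"

    def test_fully_annotated_run_adds_no_names(self, library, params):
        amps = {"Glycine": 1.0}
        ms = simulate_jres(library, amps, params)
        corr = simulate_correlations(library, amps, params)
        anns = annotate_mixture(ms, corr, library)
        assert all(not (a.assigned_name or "").startswith("Unknown") for a in anns)

    def test_unassigned_singlet_with_p31_is_level3_phosphorylated(self, library, params):
        amps = {"M4": 1.0}
        ms = simulate_jres(library, amps, params)
        corr = simulate_correlations(library, amps, params)
        anns = annotate_mixture(ms, corr, library)
        assert len(anns) == 1
        ann = anns[0]
        assert ann.assigned_name == "Unknown M1"
        assert ann.compound_class == "phosphorylated compound"
        assert ann.confidence_level == "3"
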