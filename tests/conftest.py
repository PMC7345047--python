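"""Shared fixtures: the packaged catalogue, default geometry, one full run.

The full-evidence pipeline run (every catalogued metabolite, zero noise and
dropout, spike experiments for all flagged standards plus the informative
negatives) is expensive enough to share session-wide; annotation-level tests
all read from it.
"""

from __future__ import annotations

import warnings

import pytest

from nmrannotate.library import ReferenceLibrary, load_packaged_library
from nmrannotate.pipeline import PipelineConfig, run_pipeline
from nmrannotate.simulate import SimulationParams


@pytest.fixture(scope="session")
def library() -> ReferenceLibrary:
    return load_packaged_library()


@pytest.fixture(scope="session")
def params() -> SimulationParams:
    return SimulationParams(rng_seed=1)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Full-evidence pipeline result on the complete catalogue mixture."""
    outdir = tmp_path_factory.mktemp("full_run")
    cfg = PipelineConfig(
        seed=1,
        output_dir=str(outdir),
        spike_negatives=["Sarcosine", "UDP", "UTP", "Glucose 1-phosphate"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


def single_signal_library(lib: ReferenceLibrary, metabolite: str, shift: float) -> ReferenceLibrary:
    """A one-signal sub-library for isolated worked-example simulations."""
    sigs = [
        s
        for s in lib.signals
        if s.metabolite_name == metabolite and abs(s.shift_h1 - shift) < 1e-9
    ]
    assert sigs, f"no signal {metabolite} @ {shift}"
    return ReferenceLibrary(sigs)
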