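#!/usr/bin/env python
"""Full-evidence end-to-end annotation of the complete catalogue mixture.

Simulates the whole catalogue (zero noise, zero jitter, no evidence dropout),
runs spike re-acquisitions for every flagged standard plus the four
informative negatives, annotates, and prints the confidence tabulation.
Under full evidence the engine recovers exactly the catalogue's own levels:
17 metabolites at level 1 (spike-confirmed), 20 at level 2+, 5 at level 2-,
12 class-only unknowns at level 3, with zero contradictory arguments on any
assigned candidate.  All stage outputs land in results/full_run/.
"""

import warnings
from pathlib import Path

from nmrannotate.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "full_run"


def main() -> None:
    cfg = PipelineConfig(
        seed=1,
        output_dir=str(OUT),
        spike_negatives=["Sarcosine", "UDP", "UTP", "Glucose 1-phosphate"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(cfg)

    counts = result.level_counts()
    print(
        f"named metabolites: {len(result.named_levels())} "
        f"(level 1: {counts.get('1', 0)}, 2+: {counts.get('2+', 0)}, "
        f"2-: {counts.get('2-', 0)})"
    )
    n_level3 = sum(
        1 for a in result.unknown_annotations() if a.confidence_level == "3"
    )
    print(f"unknown signal groups named: {len(result.unknown_annotations())} "
          f"({n_level3} with a level-3 compound class)")
    confirmed = [n for n, o in result.spike_outcomes.items() if o.status == "confirmed"]
    print(f"spike experiments confirmed: {len(confirmed)}")
    for name in ("Sarcosine", "UDP", "UTP", "Glucose 1-phosphate"):
        print(f"  {name}: {result.spike_outcomes[name].status}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
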