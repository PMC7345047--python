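# nmrannotate

Multi-evidence annotation of complex ¹H NMR metabolome spectra, built around
the workflow used to interpret a whole-body reference spectrum of the zebra
mussel (*Dreissena polymorpha*), a sentinel organism for freshwater
ecotoxicology.  Annotating such a spectrum is hard because hundreds of
overlapping signals must each be tied to a metabolite with defensible
confidence: a chemical-shift match alone is not an identification.  The
package implements the full evidence chain —

1. **multiplet analysis**: read the 1D spectrum with the J-resolved
   projection; classify each signal (s/d/t/q/dd/qd or unresolved m) with its
   centre δ and coupling constant J;
2. **spin-system assembly**: group signals correlated in COSY/TOCSY into
   connected components, so candidates are checked against *all* signals of a
   metabolite simultaneously;
3. **coherence matching**: compare each system with a reference library;
   count every ¹H shift, multiplicity, J, ¹H-¹³C HSQC and ¹H-³¹P argument as
   coherent or contradictory; assign only with **> 2 coherent arguments and
   zero contradictions**;
4. **confidence levelling** on an MSI-adapted scale: level 1 (confirmed by
   spiking), 2+ (several 2D confirmations), 2− (at most one confirmation, or
   a poorly referenced compound), 3 (compound class only), plus sequential
   "Unknown Mx" naming of unmatched signal groups;
5. **spike-in confirmation**: standard addition either grows every catalogue
   line of the compound (→ level 1), produces new lines that refute a
   putative candidate, or shows the compound is below the detection level;
6. **metabolite-aware bucketing**: one intelligent bucket per multiplet,
   merged into one statistical variable per annotated metabolite, with the
   bucket–metabolite association table.

The packaged reference library transcribes the printed signal catalogue
(42 named metabolites, 149 signals, confidence levels and spiked flags) and
is the single source of truth for simulation, matching and the acceptance
counts.  A synthetic-acquisition module renders 1D spectra on the study's
geometry (600 MHz, 20 ppm spectral width, 128k points, TSP at 0 ppm, 0.3 Hz
exponential broadening), JRES-style multiplet tables, correlation lists and
spike re-acquisitions with known ground truth, so the whole pipeline is
exercised end to end without raw data.

## Worked example

Simulate the full catalogue mixture with spike experiments and annotate it:

```bash
python analysis/03_full_annotation.py
```

prints

```
named metabolites: 42 (level 1: 17, 2+: 20, 2-: 5)
unknown signal groups named: 12 (12 with a level-3 compound class)
spike experiments confirmed: 17
  Sarcosine: invalidated
  UDP: undetectable
  UTP: undetectable
  Glucose 1-phosphate: undetectable
```

Under full evidence (no noise, no dropout, spikes for every flagged
standard) the engine reproduces the catalogue's own confidence levels
exactly: the 17 spike-confirmed metabolites at level 1, the 20 putative ones
at 2+, the five poorly referenced ones at 2−, and the 12 class-only signal
groups as level-3 unknowns ("sugar 1-phosphate", "nucleotide/nucleoside",
"phosphorylated compound", "acetylated compound").  The sarcosine spike is
refuted by a coincident foreign line plus a new line — the situation that
showed sarcosine was below the detection level — and the UDP/UTP/glucose
1-phosphate spikes yield only new lines, hence "undetectable".

The other numbered drivers run the remaining analyses: `01_library_census.py`
(the 17/20/37/5 counts and the 15/7/3/7/2/3 class breakdown),
`02_worked_examples.py` (all 103 resolved catalogue signals recovered at
printed multiplicity within one grid step, e.g. the alanine methyl doublet at
1.48301 ppm vs the printed 1.483), `04_spike_outcomes.py` (the three
standard-addition scenarios) and `05_bucketing.py` (930 uniform buckets →
140 intelligent buckets → 55 merged features, intensity conserved).  Tables
land under `results/`.

There is also a CLI:

```bash
nmrannotate validate-library          # parse + invariants + census
nmrannotate simulate --seed 1 -m Glycine --out glycine.jdx
nmrannotate run --seed 1 --out out/   # the full pipeline
nmrannotate report out/
```

Spectra are read and written as JCAMP-DX (AFFN; PAC also read); every table
is delimiter-separated text with a provenance header (version, configuration
hash, seed), and runs with the same configuration are byte-identical.

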