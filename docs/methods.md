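# Methods

`nmrannotate` re-implements, as a tested pipeline, the multi-evidence
annotation workflow used to interpret a whole-body ¹H NMR reference spectrum
of the zebra mussel (*Dreissena polymorpha*): read the 1D spectrum with the
help of the 2D J-resolved projection, assemble spin systems from homonuclear
correlations, match them against reference data under an explicit coherence
rule, confirm assignments by standard addition, and prepare the annotated
spectrum for multivariate statistics by metabolite-aware bucketing.  Because
the raw acquisitions are not part of the package, a synthetic-data module
generates all inputs from the packaged signal catalogue with known ground
truth; the catalogue itself is the oracle for the end-to-end checks.

## The reference signal catalogue

`src/nmrannotate/data/reference_library.tsv` is a machine transcription of
the printed signal catalogue: 42 named metabolites (149 signal rows in
total), each signal with its ¹H shift, multiplicity, confidence level and
spiked flag.  Conventions:

- A bare printed peak count "(k)" (a shape that could not be confirmed on the
  J-resolved spectrum) is stored as multiplicity `m` with `n_peaks = k`.
- The one range entry (the NMN doublet) is stored at the range midpoint with
  the printed bounds kept as metadata; only the bounds are authoritative.
- The catalogue prints no ¹³C shifts, but the method requires HSQC evidence,
  so `c13_ppm` carries literature-typical (HMDB-style) values.  They are used
  *self-consistently*: the simulator emits them and the matcher compares
  against the same column, so their absolute accuracy does not affect any
  result; their relative spacing does (e.g. the lactate/threonine methyl
  doublets at 1.331/1.333 ppm are separated by their δC, 22.9 vs 22.2 ppm,
  exactly as HSQC separates them in practice).  Signals reported without ¹³C
  evidence (allantoin, GABA, NMN) carry none.
- Class-only level-3 records (M2, M4, M7, M8, M11, M12, M13–M18) and the four
  informative-negative spike standards (sarcosine, UDP, UTP, glucose
  1-phosphate) have no printed shifts; their placements are synthetic, chosen
  once inside the narratively described regions (the 5.5 ppm doublet-pair
  region, the 5.75–6.25 ppm nucleoside H1′ region, the acetyl region, the
  two ³¹P-correlated singlet positions) and at least one matching tolerance
  away from every printed shift.  The library header labels them synthetic.
- Spike standards carry level `unknown` and are excluded from all confidence
  tabulations; they participate in database matching (sarcosine is a real
  database compound — that is the point of the sarcosine episode).
- A `poorly_referenced` flag marks the five level-2− metabolites
  (phosphocholine, glycerophosphocholine, allantoin, GABA, NMN).  The 2−
  definition explicitly covers compounds poorly referenced in the databases;
  GABA in particular carries full homonuclear evidence and would otherwise
  reach 2+, but its duplicated-triplet anomaly kept it putative.  The flag
  caps putative levels at 2−; it never caps a direct spike confirmation.
- Counted discrepancies in the source summary (5 vs 3 carbohydrates; "20
  unknown groups" named up to M23 vs "23 unidentified metabolites") are
  resolved in favour of the printed table; the ambiguity is noted here and
  not modelled.

## Synthetic acquisitions

`simulate.py` renders what the study's instrument produced, on the study's
geometry — all defaults are the stated acquisition conditions:

| parameter | default | meaning |
|---|---|---|
| `spectrometer_freq` | 600.0 MHz | ppm↔Hz conversion; the 800 MHz re-acquisitions are represented only by this parameter |
| `spectral_width` / `n_points` | 20 ppm / 131072 | the 128k acquisition grid; one grid step ≈ 0.00015 ppm |
| `linewidth_fwhm` + `broadening` | 1.0 + 0.3 Hz | Lorentzian FWHM; the exponential window adds linearly |
| `noise_sd`, `shift_jitter_sd`, `tsp_offset`, `evidence_dropout` | 0 | imperfections injected per experiment |
| `rng_seed` | — | every random draw derives from it |

Multiplets are first-order: binomial s/d/t/q patterns, tensor products for
dd/qd, line spacing J/ν₀ ppm.  The catalogue prints no J values; defaults are
literature-typical by region (7.0 Hz aliphatic, 8.0 Hz aromatic, 3.8/8.0 Hz
for α/β anomeric doublets), applied by the same deterministic rule on the
simulation and matching sides, overridable per signal in the library file.
Unresolved `m` signals render as 2k−1 lines with jittered spacings and are
flagged unclassifiable in the ground truth; `br` renders as one six-fold
broadened line.  Line weights are normalized so integrated multiplet area is
proportional to amplitude and independent of multiplicity.  A reference
miscalibration (`tsp_offset`) displaces the *whole* axis labelling — TSP and
metabolite lines alike — so referencing recovers the true positions.

Per-signal randomness (jitter, m-line placement) comes from a sub-generator
keyed by the signal identity, so a spiked re-acquisition reproduces the same
lines regardless of evaluation order, and identical (inputs, seed) give
bit-identical outputs.

Beyond the 1D trace the simulator emits the 2D-derived evidence the paper's
workflow reads: a JRES-style multiplet table (one classified multiplet per
signal — this is what resolves the coincident lactate/threonine and
glucose/maltose lines that the 1D trace cannot), COSY edges between
consecutive members of a spin system and the TOCSY clique over it, ¹H-¹³C
HSQC pairs emitted once per field (600 and 800 MHz — the study validated
every correlation on both instruments, which is why a lone singlet with a δC
can reach "more than one confirmation"), and ¹H-³¹P pairs for flagged
signals.  Spin-system topology is encoded per signal in the library
(`spin_group`): uncoupled groups of one metabolite (the two betaine singlets,
histidine's CH₂ vs its ring proton, the adenine H2/H8 singlets) are separate
systems, as they are physically.

What the generator does *not* emulate, hence what passing tests do not show:
second-order (strong-coupling) lineshapes, baseline/phase distortions,
solvent suppression artefacts, pH-dependent shift drift beyond Gaussian
jitter, and relaxation-dependent intensity effects.  Recovery rates on real
spectra will be lower than on these synthetic ones; the end-to-end test
demonstrates the *logic* of the evidence rules, not field performance.

## Signal processing

`reference_to_tsp` finds the tallest point within ±0.3 ppm of 0, refines the
apex by 3-point parabolic interpolation and translates the axis (idempotent;
error "reference not found" when no candidate exists).  `pick_peaks` takes
local maxima above `snr_threshold` × a robust noise estimate (1.4826 × MAD
over 9.5–10 ppm, a signal-free region by construction; on noiseless spectra a
10⁻⁶-of-maximum floor substitutes), refines apexes parabolically and excludes
the TSP region.  `group_multiplets` clusters peaks closer than 20 Hz (the
JRES F1 window), then segments each cluster into classifiable runs: equal
spacing within ±0.3 Hz and binomial intensity ratios within ±25% give
s/d/t/q; a symmetric four-line a-b-a pattern of equal intensities gives dd;
anything else is an unresolved `m`.  A gap below 1.5 Hz (unresolvable at the
~1.3 Hz linewidth) marks the whole cluster unresolved — coincident multiplets
cannot be separated on the 1D trace, only on the J dimension.  Tolerances are
generous against the 0.09 Hz grid resolution.

## Annotation engine

Spin systems are connected components of the homonuclear edge graph
(dangling endpoints are dropped with a warning; uncorrelated multiplets are
singletons).  For every system, `match_library` builds an evidence ledger
over all database candidates sharing at least one ¹H shift within tolerance
(defaults ±0.03 ppm ¹H, ±0.5 ppm ¹³C, ±0.5 Hz J — the sources print no
tolerance; shifts vary with sample pH, so these are configurable decisions).
Arguments counted per aligned signal: the ¹H shift, the multiplicity
agreement, the J agreement where both sides carry one, each δC observation,
each ³¹P verdict, plus one argument per homonuclear edge consistent with the
candidate's topology.  Contradictions: a resolved-shape mismatch (a counted
`m(k)` is *neutral* against a letter implying k lines — the shape merely
could not be confirmed), a J or δC disagreement beyond tolerance, a ³¹P
correlation on a candidate not marked phosphorylated (and vice versa when the
³¹P experiment was acquired), and a candidate signal expected in the spectrum
but absent.  Two deliberate scope rules for that last check: it scans the
*whole* multiplet table, not the system (metabolites legitimately span
several uncoupled systems), and signals inside the crowded regions
(3.6–4.4 and 1.80–1.94 ppm by default) are exempt — those regions are not
annotated at all, mirroring the study's refusal (it could not even look for
ornithine there).

Assignment requires more than two coherent arguments and zero contradictions.
Among eligible candidates, more coherent arguments win, then the smaller RMS
¹H deviation; an exact tie keeps both names and caps the level at 2− (the
study resolves such ties only by spiking).  Per-system winners are pooled per
metabolite before the confidence decision, because confidence is a property
of the metabolite and uncoupled signal groups of one compound corroborate
each other (betaine's two singlets with two δC matches each are the canonical
case).  Levels: spike-confirmed → 1; ≥3 coherent arguments with ≥2 2D
confirmations → 2+; a coherent shift with at most one confirmation → 2−
(this covers both "only one confirmation" and shift-only matches);
`poorly_referenced` caps 2+ at 2−.

Spike evaluation compares the post- minus pre-spike difference at every
expected line of the standard against the standard's known relative line
intensities — spectra are additive, so this detects genuine growth even under
co-resonating neighbours (an apex-ratio test fails for weak lines of
multiplet-rich compounds overlapped by stronger signals, e.g. the 15-line
lysine cluster under the alanine doublet).  Coincidence uses a ±0.005 ppm
re-acquisition tolerance, much tighter than the database tolerance, because
pre and post spectra come from the same sample and instrument.  Outcomes:
all lines coincident and grown → confirmed (level 1); no pre-existing line →
the standard was under the detection level; mixed → whatever candidate rode
on those positions is refuted (the sarcosine outcome).  A refuted candidate's
annotation is unassigned and its ledger records a contradictory spike item.

Remaining unassigned systems receive compound-class heuristics in fixed
order: two or more doublets in 5.35–5.60 ppm → "sugar 1-phosphate" (the
anomeric doublet-pair motif; a ³¹P pair strengthens but is not required —
the weaker of the two such groups fell below the ³¹P detection threshold in
the study); all members in 5.75–6.25 ppm → "nucleotide/nucleoside" (the
ribose H1′/uracil H5 region); a singlet in 1.95–2.10 ppm with δC 20–26 →
"acetylated compound"; any ³¹P pair → "phosphorylated compound".  Unassigned
multi-signal systems and well-defined singlets are then named "Unknown M1,
M2, …" in downfield order.  The numbering is self-consistent but cannot match
the study's appendix codes, which are not reproduced in the printed text.

## Bucketing

`uniform_buckets` slices a window (default 0.5–10 ppm, residual-water band
4.7–4.9 ppm excluded) into equal parts (default 0.01 ppm, reading the
source's "small equal parts" as hundredths of a ppm).  `intelligent_buckets`
aligns one bucket per multiplet, spanning its outermost lines ±2×FWHM;
overlapping neighbours share a boundary at the intensity minimum inside the
overlap window, clamped strictly between the two centres so a narrow signal
nested inside a wide neighbour's span keeps a non-degenerate bucket;
multiplets coincident within one grid step share one bucket with a warning
(a bucket genuinely shared by two metabolites is assigned to neither name's
exclusive credit — it is flagged by the warning and merged under the first).
Integration is trapezoidal with endpoint interpolation at the exact bounds,
so contiguous buckets telescope to the window integral.  `merge_buckets`
sums the buckets of each annotated metabolite into one feature — ideally a
single variable per metabolite — passes unannotated buckets through, and
writes the bucket-metabolite association table.  Total intensity is
conserved exactly.

## Pipeline, formats, provenance

`run_pipeline` chains simulate → reference → pick → group (JRES-tagged by
default; pure 1D by configuration) → spin systems → match → spike → decide →
name unknowns → bucket → merge, persisting every stage as delimiter-separated
text with a provenance header (tool version, configuration hash, seed).
Spectra travel as JCAMP-DX: AFFN (plain-number) writing for bit-auditable
files, AFFN and PAC reading, compressed dialects refused by name; peak
annotations embed as a `##PEAK TABLE=(XYA)` block.  The CLI (`nmrannotate`)
exposes `run`, `simulate`, `annotate`, `bucket`, `report` and
`validate-library`, each runnable independently on persisted intermediates.

## Problem sizes and demonstration conditions

The demonstration mixture is the complete catalogue (54 simulated entities,
~140 multiplets on the 131k grid) with unit amplitudes except the four
dominant resting-period metabolites (putrescine, trimethylamine, succinate,
betaine at 5–6×), zero noise/jitter/dropout — the full-evidence condition
under which the engine must reproduce the catalogue's own levels exactly:
17 level-1, 20 level-2+, 5 level-2−, 12 level-3 class-only unknowns, zero
contradictions.  The run, including 21 spike re-acquisitions, completes in
well under a minute on one CPU.  The study's full 238-signal census depends
on its unpublished appendix and is not reproducible from the printed text;
it is outside the package's acceptance surface.

## Known limitations

- First-order multiplets only; strong coupling, roofing and second-order
  patterns are absent, so classification accuracy on real 600 MHz spectra of
  closely coupled systems will be lower.
- The evidence calculus treats each correlation as one argument; it does not
  weight by intensity or by how diagnostic a region is.
- Level-3 class rules are region heuristics tuned to this catalogue's
  regions; other matrices would need different windows.
- The `poorly_referenced` flag encodes expert knowledge in the library rather
  than deriving it from database coverage statistics.
- The 1D-only multiplet grouping is a fallback; in crowded mixtures it
  merges coincident signals by design and should not be used for annotation
  when a J-resolved table is available.
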