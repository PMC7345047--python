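"""End-to-end pipeline: simulate -> reference -> read -> annotate -> bucket.

``run_pipeline`` executes the full chain on a configured mixture and persists
every stage's output as delimiter-separated text with provenance headers
(tool version, configuration hash, seed), so each stage can also be re-run
independently from the CLI on the persisted intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    Annotation,
    AnnotationConfig,
    MatchTolerances,
    SpikeOutcome,
    annotate_mixture,
    evaluate_spike,
)
from .bucketing import intelligent_buckets, merge_buckets
from .jcamp import write_jcampdx
from .library import ReferenceLibrary, load_library, load_packaged_library
from .processing import group_multiplets, pick_peaks, reference_to_tsp
from .simulate import (
    SimulationParams,
    Spectrum1D,
    demo_amplitudes,
    simulate_correlations,
    simulate_jres,
    simulate_spectrum,
    simulate_spike,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("nmrannotate")


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "pipeline_out"
    library_path: str | None = None  # None -> packaged catalogue
    # simulation
    noise_sd: float = 0.0
    shift_jitter_sd: float = 0.0
    tsp_offset: float = 0.0
    evidence_dropout: float = 0.0
    spectrometer_freq: float = 600.0
    amplitudes: dict[str, float] | None = None  # None -> full demo mixture
    # processing
    snr_threshold: float = 5.0
    multiplet_source: str = "jres"  # "jres" (id-tagged) or "1d" (trace only)
    # annotation
    h1_tolerance: float = 0.03
    c13_tolerance: float = 0.5
    j_tolerance: float = 0.5
    crowded_regions: tuple[tuple[float, float], ...] = ((3.6, 4.4), (1.80, 1.94))
    # spikes
    run_spikes: bool = True
    spike_metabolites: list[str] | None = None  # None -> all flagged level-1
    spike_negatives: list[str] = field(default_factory=list)
    spike_fold: float = 5.0
    spike_min_fold: float = 2.0
    spike_position_tol: float = 0.005
    # bucketing
    bucket_window: tuple[float, float] = (0.5, 10.0)
    bucket_exclusions: tuple[tuple[float, float], ...] = ((4.7, 4.9),)
    uniform_bucket_width: float = 0.01
    write_spectrum: bool = False

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(
            spectrometer_freq=self.spectrometer_freq,
            noise_sd=self.noise_sd,
            shift_jitter_sd=self.shift_jitter_sd,
            tsp_offset=self.tsp_offset,
            evidence_dropout=self.evidence_dropout,
            rng_seed=self.seed,
        )

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(
            tolerances=MatchTolerances(
                h1_ppm=self.h1_tolerance,
                c13_ppm=self.c13_tolerance,
                j_hz=self.j_tolerance,
            ),
            crowded_regions=tuple(tuple(r) for r in self.crowded_regions),
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration; unknown keys are rejected."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    valid = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("crowded_regions", "bucket_exclusions"):
        if key in raw:
            raw[key] = tuple(tuple(r) for r in raw[key])
    if "bucket_window" in raw:
        raw["bucket_window"] = tuple(raw["bucket_window"])
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    library: ReferenceLibrary
    spectrum: Spectrum1D
    ground_truth: dict
    multiplets: list
    correlations: Any
    annotations: list[Annotation]
    spike_outcomes: dict[str, SpikeOutcome]
    features: pd.DataFrame
    association: pd.DataFrame

    def named_levels(self) -> dict[str, str]:
        """Assigned metabolite -> confidence level (Unknowns excluded)."""
        out: dict[str, str] = {}
        for ann in self.annotations:
            name = ann.assigned_name
            if name is None or name.startswith("Unknown "):
                continue
            out[name] = ann.confidence_level
        return out

    def level_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for level in self.named_levels().values():
            counts[level] = counts.get(level, 0) + 1
        return counts

    def unknown_annotations(self) -> list[Annotation]:
        return [
            a
            for a in self.annotations
            if a.assigned_name is not None and a.assigned_name.startswith("Unknown ")
        ]


def _provenance(config: PipelineConfig) -> str:
    return (
        f"# nmrannotate v{__version__}\tseed={config.seed}\t"
        f"config_hash={config.config_hash()}"
    )


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(config) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full annotation pipeline and persist every stage's output."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.library_path is not None:
        lib_path = Path(config.library_path)
        if not lib_path.exists():
            raise FileNotFoundError(f"library file not found: {lib_path}")
        lib = load_library(lib_path)
    else:
        lib = load_packaged_library()
    params = config.simulation_params()
    amplitudes = (
        dict(config.amplitudes) if config.amplitudes is not None else demo_amplitudes(lib)
    )
    log.info("simulating %d-metabolite mixture", len(amplitudes))
    raw_spectrum, truth = simulate_spectrum(lib, amplitudes, params)
    spectrum = reference_to_tsp(raw_spectrum)
    peaks = pick_peaks(spectrum, config.snr_threshold)
    if config.multiplet_source == "jres":
        multiplets = simulate_jres(lib, amplitudes, params)
    else:
        multiplets = group_multiplets(
            peaks, spectrometer_freq=params.spectrometer_freq
        )
    corr = simulate_correlations(lib, amplitudes, params)
    log.info(
        "processing: %d peaks, %d multiplets, %d homonuclear edges (%.1fs)",
        len(peaks), len(multiplets), len(corr.homonuclear_edges), time.time() - t0,
    )

    spike_outcomes: dict[str, SpikeOutcome] = {}
    if config.run_spikes:
        targets = config.spike_metabolites
        if targets is None:
            targets = [
                name
                for name, sigs in lib.metabolites.items()
                if sigs[0].spiked and sigs[0].confidence_level == "1"
            ]
        for name in list(targets) + list(config.spike_negatives):
            post = simulate_spike(
                spectrum, truth, lib, name, config.spike_fold, params
            )
            spike_outcomes[name] = evaluate_spike(
                spectrum,
                post,
                lib,
                name,
                min_fold=config.spike_min_fold,
                position_tol=config.spike_position_tol,
                ground_truth=truth,
                pre_peaks=peaks,
            )
        log.info("spiking: %d experiments (%.1fs)", len(spike_outcomes), time.time() - t0)

    annotations = annotate_mixture(
        multiplets, corr, lib, config.annotation_config(), spike_outcomes
    )
    buckets = intelligent_buckets(spectrum, multiplets)
    features, association = merge_buckets(buckets, annotations)
    result = PipelineResult(
        config=config,
        library=lib,
        spectrum=spectrum,
        ground_truth=truth,
        multiplets=multiplets,
        correlations=corr,
        annotations=annotations,
        spike_outcomes=spike_outcomes,
        features=features,
        association=association,
    )
    _persist(result, peaks, buckets, outdir)
    log.info("pipeline complete (%.1fs)", time.time() - t0)
    return result


def _persist(result: PipelineResult, peaks, buckets, outdir: Path) -> None:
    cfg = result.config
    by_id = {m.signal_id: m for m in result.multiplets}
    rows = []
    for ann in sorted(result.annotations, key=lambda a: -a.centre):
        members = sorted(ann.system.member_ids, key=lambda i: -by_id[i].centre)
        for sid in members:
            m = by_id[sid]
            ev = ann.ledger.get(ann.assigned_name) if ann.assigned_name else None
            rows.append(
                {
                    "signal_id": sid,
                    "centre_ppm": round(m.centre, 4),
                    "multiplicity": m.multiplicity
                    + (str(m.n_peaks) if m.multiplicity == "m" and m.n_peaks else ""),
                    "j_hz": "" if m.j_est is None else round(m.j_est, 2),
                    "assignment": ann.assigned_name or "",
                    "class": ann.compound_class,
                    "level": ann.confidence_level,
                    "evidence": _evidence_summary(ann),
                }
            )
    _write_table(pd.DataFrame(rows), outdir / "annotations.tsv", cfg)
    _write_table(
        pd.DataFrame(
            [
                {"position_ppm": round(p.position, 4), "intensity": p.intensity,
                 "fwhm_hz": round(p.fwhm_hz, 2)}
                for p in peaks
            ]
        ),
        outdir / "peaks.tsv",
        cfg,
    )
    _write_table(
        pd.DataFrame(
            [
                {"bucket_left": round(b.left, 4), "bucket_right": round(b.right, 4),
                 "intensity": b.intensity, "signal_id": b.signal_id}
                for b in buckets
            ]
        ),
        outdir / "buckets.tsv",
        cfg,
    )
    _write_table(result.features, outdir / "features.tsv", cfg)
    _write_table(result.association, outdir / "association.tsv", cfg)
    _write_table(
        pd.DataFrame(
            [
                {"metabolite": o.metabolite, "status": o.status, "n_lines": o.n_lines,
                 "n_pre_existing": o.n_pre_existing, "n_grew": o.n_grew, "n_new": o.n_new}
                for o in result.spike_outcomes.values()
            ]
        ),
        outdir / "spike_outcomes.tsv",
        cfg,
    )
    (outdir / "report.txt").write_text(render_report(result), encoding="utf-8")
    if cfg.write_spectrum:
        write_jcampdx(
            result.spectrum,
            outdir / "spectrum.jdx",
            comments=[_provenance(cfg).lstrip("# ")],
            peak_annotations=[
                (by_id[sid].centre, by_id[sid].area, ann.assigned_name)
                for ann in result.annotations
                if ann.assigned_name
                for sid in ann.system.member_ids
            ],
        )


def _evidence_summary(ann: Annotation) -> str:
    if ann.assigned_name is None or ann.assigned_name.startswith("Unknown "):
        if ann.compound_class:
            return f"class evidence: {ann.compound_class}"
        return ""
    ev = ann.ledger.get(ann.assigned_name)
    if ev is None:
        return ""
    kinds: dict[str, int] = {}
    for item in ev.coherent:
        kinds[item.etype] = kinds.get(item.etype, 0) + 1
    return ",".join(f"{k}x{v}" for k, v in sorted(kinds.items()))


def render_report(result: PipelineResult) -> str:
    """Human-readable summary of the annotation run."""
    cfg = result.config
    levels = result.named_levels()
    counts = result.level_counts()
    lines = [
        f"nmrannotate v{__version__} annotation report",
        f"seed={cfg.seed} config_hash={cfg.config_hash()}",
        "",
        f"spin systems annotated: {len(result.annotations)}",
        f"named metabolites: {len(levels)}"
        f" (level 1: {counts.get('1', 0)}, 2+: {counts.get('2+', 0)},"
        f" 2-: {counts.get('2-', 0)})",
        f"unknowns named: {len(result.unknown_annotations())}",
        "",
        "metabolite\tlevel",
    ]
    for name in sorted(levels, key=lambda n: (levels[n], n)):
        lines.append(f"{name}\t{levels[name]}")
    if result.spike_outcomes:
        lines += ["", "spike experiments:"]
        for name, o in sorted(result.spike_outcomes.items()):
            lines.append(f"{name}\t{o.status}")
    unknowns = sorted(result.unknown_annotations(), key=lambda a: -a.centre)
    if unknowns:
        lines += ["", "unknown signal groups:"]
        for ann in unknowns:
            cls = f" [{ann.compound_class}]" if ann.compound_class else ""
            lvl = f" level {ann.confidence_level}" if ann.confidence_level != "unassigned" else ""
            lines.append(f"{ann.assigned_name}\t{ann.centre:.3f} ppm{cls}{lvl}")
    return "\n".join(lines) + "\n"
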