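"""Synthetic acquisition emulator.

Renders, from reference-library entries, the artefacts the annotation pipeline
consumes: a 1D 1H spectrum on the acquisition grid (20 ppm spectral width,
128k points, TSP reference at 0 ppm, Lorentzian lines with 0.3 Hz exponential
broadening on top of the natural linewidth), a JRES-style multiplet table, the
homonuclear (COSY/TOCSY) and heteronuclear (1H-13C HSQC at two fields,
1H-31P HSQC-TOCSY) correlation lists, and spike-in re-acquisitions.

Everything is deterministic given ``SimulationParams.rng_seed``; per-signal
randomness (chemical-shift jitter, unresolved-multiplet line placement) is
drawn from a sub-generator keyed by the signal identity so that re-renderings
(e.g. the spiked re-acquisition) reproduce the same lines regardless of call
order.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .library import ReferenceLibrary, ReferenceSignal, LibraryError
from .processing import Multiplet, Peak

__all__ = [
    "SimulationParams",
    "Spectrum1D",
    "CorrelationSet",
    "GroundTruthEntry",
    "simulate_multiplet",
    "simulate_spectrum",
    "simulate_jres",
    "simulate_correlations",
    "simulate_spike",
    "expected_lines",
    "expected_line_positions",
    "demo_amplitudes",
]


@dataclass(frozen=True)
class SimulationParams:
    """Acquisition-geometry and noise parameters of the emulated experiment."""

    spectrometer_freq: float = 600.0  # MHz; 1 ppm = this many Hz
    spectral_width: float = 20.0  # ppm
    n_points: int = 131072  # 128k real points
    axis_max: float = 15.0  # downfield edge of the grid, ppm
    linewidth_fwhm: float = 1.0  # natural Lorentzian FWHM, Hz
    broadening: float = 0.3  # exponential window equivalent, Hz
    noise_sd: float = 0.0  # additive Gaussian noise, intensity units
    shift_jitter_sd: float = 0.0  # per-signal shift jitter, ppm
    tsp_offset: float = 0.0  # reference miscalibration to inject, ppm
    tsp_amplitude: float = 3.0
    rng_seed: int = 0
    evidence_dropout: float = 0.0  # per-correlation deletion probability

    def __post_init__(self) -> None:
        if self.n_points <= 0 or self.spectral_width <= 0:
            raise ValueError("n_points and spectral_width must be positive")
        if not 0.0 <= self.evidence_dropout <= 1.0:
            raise ValueError("evidence_dropout must be in [0, 1]")

    @property
    def fwhm_total_hz(self) -> float:
        return self.linewidth_fwhm + self.broadening

    @property
    def grid_step(self) -> float:
        return self.spectral_width / (self.n_points - 1)

    def ppm_axis(self) -> np.ndarray:
        """Descending ppm grid (high field on the right, NMR convention)."""
        return np.linspace(
            self.axis_max, self.axis_max - self.spectral_width, self.n_points
        )


@dataclass
class Spectrum1D:
    """A 1D spectrum: descending ppm axis plus intensities."""

    ppm: np.ndarray
    intensities: np.ndarray
    params: SimulationParams
    referenced: bool = False

    def __post_init__(self) -> None:
        if len(self.ppm) != len(self.intensities):
            raise ValueError("axis and intensity lengths differ")
        if not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly descending")

    def index_of(self, ppm: float) -> int:
        return int(np.argmin(np.abs(self.ppm - ppm)))

    def intensity_at(self, ppm: float) -> float:
        return float(self.intensities[self.index_of(ppm)])

    def copy(self) -> "Spectrum1D":
        return Spectrum1D(
            self.ppm.copy(), self.intensities.copy(), self.params, self.referenced
        )


@dataclass
class GroundTruthEntry:
    signal_id: int
    metabolite: str
    shift: float  # jittered multiplet centre actually rendered, ppm
    multiplicity: str
    n_peaks: int | None
    j_values: tuple[float, ...]
    amplitude: float
    line_positions: tuple[float, ...]
    line_weights: tuple[float, ...]
    unclassifiable: bool


@dataclass
class CorrelationSet:
    """2D-derived evidence: edge lists keyed by simulated signal ids."""

    homonuclear_edges: list[tuple[int, int, str]] = field(default_factory=list)
    hsqc_pairs: list[tuple[int, float, int]] = field(default_factory=list)  # (id, dC, field MHz)
    p31_pairs: list[tuple[int, float]] = field(default_factory=list)  # (id, dP)

    def is_empty(self) -> bool:
        return not (self.homonuclear_edges or self.hsqc_pairs or self.p31_pairs)


def _signal_rng(seed: int, sig: ReferenceSignal, salt: str = "") -> np.random.Generator:
    key = f"{seed}|{sig.metabolite_name}|{sig.shift_h1}|{salt}".encode()
    sub = int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
    return np.random.default_rng([seed & 0x7FFFFFFF, sub])


def _pattern_lines(sig: ReferenceSignal, rng: np.random.Generator) -> tuple[
    np.ndarray, np.ndarray, bool
]:
    """Line offsets (Hz, centred) and normalized weights for one signal."""
    mult = sig.multiplicity
    j = sig.effective_j
    if mult == "s":
        return np.array([0.0]), np.array([1.0]), False
    if mult in ("d", "t", "q"):
        n = {"d": 2, "t": 3, "q": 4}[mult]
        offs = (np.arange(n) - (n - 1) / 2.0) * j[0]
        w = np.array([float(math.comb(n - 1, k)) for k in range(n)])
        return offs, w / w.sum(), False
    if mult in ("dd", "qd"):
        if mult == "dd":
            a_offs, a_w = np.array([-0.5, 0.5]) * j[0], np.array([1.0, 1.0])
        else:  # quartet of doublets
            a_offs = (np.arange(4) - 1.5) * j[0]
            a_w = np.array([1.0, 3.0, 3.0, 1.0])
        b_offs, b_w = np.array([-0.5, 0.5]) * j[1], np.array([1.0, 1.0])
        offs = (a_offs[:, None] + b_offs[None, :]).ravel()
        w = (a_w[:, None] * b_w[None, :]).ravel()
        order = np.argsort(offs)
        return offs[order], w[order] / w.sum(), False
    if mult == "m":
        # unresolved cluster: 2k-1 lines with jittered spacings and weights
        k = sig.n_peaks if sig.n_peaks is not None else 3
        n = 2 * k - 1
        base = (sig.effective_j[0] if sig.effective_j else 7.0) / 2.0
        spacings = base * (1.0 + 0.2 * rng.uniform(-1, 1, size=max(n - 1, 1)))
        offs = np.concatenate([[0.0], np.cumsum(spacings[: n - 1])])
        offs -= offs.mean()
        w = 0.6 + 0.4 * rng.uniform(0, 1, size=n)
        return offs, w / w.sum(), True
    if mult == "br":
        return np.array([0.0]), np.array([1.0]), True
    raise LibraryError(f"cannot simulate multiplicity {mult!r}")


def simulate_multiplet(
    sig: ReferenceSignal,
    amplitude: float,
    params: SimulationParams,
    centre: float | None = None,
) -> list[tuple[float, float]]:
    """First-order line list for one signal: (position ppm, relative intensity).

    s/d/t/q produce binomial patterns, dd/qd tensor products of doublet
    splittings; unresolved m/br signals produce a dense cluster (deterministic
    for a given seed) and are flagged unclassifiable in the ground truth.
    """
    rng = _signal_rng(params.rng_seed, sig, "m-lines")
    offs_hz, weights, _ = _pattern_lines(sig, rng)
    c = sig.shift_h1 if centre is None else centre
    positions = c + offs_hz / params.spectrometer_freq
    return [(float(p), float(w * amplitude)) for p, w in zip(positions, weights)]


def _layout(
    sig: ReferenceSignal, amplitude: float, params: SimulationParams
) -> tuple[float, np.ndarray, np.ndarray, float, bool]:
    """Rendered centre, line positions (ppm), apex weights, FWHM (Hz), flag."""
    jitter = 0.0
    if params.shift_jitter_sd > 0:
        jitter = float(
            _signal_rng(params.rng_seed, sig, "jitter").normal(
                0.0, params.shift_jitter_sd
            )
        )
    centre = sig.shift_h1 + jitter
    rng = _signal_rng(params.rng_seed, sig, "m-lines")
    offs_hz, weights, unclassifiable = _pattern_lines(sig, rng)
    positions = centre + offs_hz / params.spectrometer_freq
    fwhm = params.fwhm_total_hz * (6.0 if sig.multiplicity == "br" else 1.0)
    return centre, positions, weights * amplitude, fwhm, unclassifiable


def _render(
    ppm: np.ndarray,
    positions: Sequence[float],
    apexes: Sequence[float],
    fwhm_hz: float,
    params: SimulationParams,
) -> np.ndarray:
    hw = fwhm_hz / 2.0 / params.spectrometer_freq  # half width at half max, ppm
    y = np.zeros_like(ppm)
    for p, a in zip(positions, apexes):
        y += a * hw**2 / ((ppm - p) ** 2 + hw**2)
    return y


def _mixture_signals(
    lib: ReferenceLibrary, amplitudes: Mapping[str, float]
) -> list[tuple[int, ReferenceSignal, float]]:
    missing = set(amplitudes) - set(lib.metabolites)
    if missing:
        raise LibraryError(f"metabolites not in library: {sorted(missing)}")
    out = []
    for sid, sig in enumerate(lib.signals):
        if sig.metabolite_name in amplitudes:
            out.append((sid, sig, float(amplitudes[sig.metabolite_name])))
    return out


def simulate_spectrum(
    lib: ReferenceLibrary,
    amplitudes: Mapping[str, float],
    params: SimulationParams,
) -> tuple[Spectrum1D, dict[int, GroundTruthEntry]]:
    """Render the 1D spectrum of a mixture and its per-signal ground truth.

    Signal ids are the row indices of the library, so correlation and JRES
    tables generated from the same mixture share the id space.
    """
    ppm = params.ppm_axis()
    y = np.zeros_like(ppm)
    truth: dict[int, GroundTruthEntry] = {}
    # a reference miscalibration displaces the whole axis labelling: every
    # line (metabolite signals and TSP alike) renders shifted by tsp_offset,
    # and referencing to TSP recovers the true positions recorded in the
    # ground truth
    for sid, sig, amp in _mixture_signals(lib, amplitudes):
        centre, positions, apexes, fwhm, flag = _layout(sig, amp, params)
        y += _render(ppm, positions + params.tsp_offset, apexes, fwhm, params)
        truth[sid] = GroundTruthEntry(
            signal_id=sid,
            metabolite=sig.metabolite_name,
            shift=centre,
            multiplicity=sig.multiplicity,
            n_peaks=sig.n_peaks,
            j_values=sig.effective_j,
            amplitude=amp,
            line_positions=tuple(float(p) for p in positions),
            line_weights=tuple(float(a) for a in apexes),
            unclassifiable=flag,
        )
    # internal reference line (never part of the ground truth mapping)
    y += _render(
        ppm, [params.tsp_offset], [params.tsp_amplitude],
        params.fwhm_total_hz, params,
    )
    if params.noise_sd > 0:
        noise_rng = np.random.default_rng([params.rng_seed & 0x7FFFFFFF, 0xBEEF])
        y = y + noise_rng.normal(0.0, params.noise_sd, size=len(ppm))
    return (
        Spectrum1D(ppm, y, params, referenced=(params.tsp_offset == 0.0)),
        truth,
    )


def simulate_jres(
    lib: ReferenceLibrary,
    amplitudes: Mapping[str, float],
    params: SimulationParams,
) -> list[Multiplet]:
    """JRES-style multiplet table: one classified multiplet per signal.

    Emulates reading the 2D J-resolved spectrum (multiplicity along F1 within
    a +/-20 Hz window, shift along F2): coincident 1D peaks are resolved into
    separate multiplets because the J dimension separates them.  Unresolved
    m/br signals keep their observed peak count but are flagged
    unclassifiable.
    """
    table: list[Multiplet] = []
    for sid, sig, amp in _mixture_signals(lib, amplitudes):
        centre, positions, apexes, fwhm, flag = _layout(sig, amp, params)
        peaks = [
            Peak(position=float(p), intensity=float(a), fwhm_hz=fwhm)
            for p, a in zip(positions, apexes)
        ]
        j_est = sig.effective_j[0] if sig.multiplicity in ("d", "t", "q", "dd", "qd") else None
        table.append(
            Multiplet(
                signal_id=sid,
                centre=centre,
                multiplicity=sig.multiplicity,
                n_peaks=sig.n_peaks,
                j_est=j_est,
                peaks=sorted(peaks, key=lambda p: p.position),
                area=amp,
                unclassifiable=flag,
            )
        )
    table.sort(key=lambda m: -m.centre)  # downfield first
    return table


def simulate_correlations(
    lib: ReferenceLibrary,
    amplitudes: Mapping[str, float],
    params: SimulationParams,
) -> CorrelationSet:
    """COSY/TOCSY edges within spin systems plus HSQC and 31P pairs.

    COSY connects consecutive members of a spin system (vicinal neighbours in
    catalogue order), TOCSY the full clique.  HSQC pairs are emitted twice for
    every 13C-bearing signal - once per field (600 and 800 MHz acquisition) -
    because the study validated each correlation on both instruments.  Each
    emitted item is independently deleted with probability
    ``evidence_dropout``.
    """
    rng = np.random.default_rng([params.rng_seed & 0x7FFFFFFF, 0xC0FE])
    keep = lambda: rng.uniform() >= params.evidence_dropout  # noqa: E731
    corr = CorrelationSet()
    groups: dict[tuple[str, str], list[int]] = {}
    members = _mixture_signals(lib, amplitudes)
    for sid, sig, _ in members:
        groups.setdefault((sig.metabolite_name, sig.spin_group), []).append(sid)
    for ids in groups.values():
        for a, b in zip(ids, ids[1:]):
            if keep():
                corr.homonuclear_edges.append((a, b, "COSY"))
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if keep():
                    corr.homonuclear_edges.append((a, b, "TOCSY"))
    for sid, sig, _ in members:
        if sig.shift_c13 is not None:
            for fld in (600, 800):
                if keep():
                    corr.hsqc_pairs.append((sid, sig.shift_c13, fld))
        if sig.has_p31_correlation:
            if keep():
                corr.p31_pairs.append((sid, sig.p31_shift if sig.p31_shift is not None else 0.0))
    return corr


def expected_lines(
    lib: ReferenceLibrary,
    metabolite: str,
    params: SimulationParams,
    ground_truth: Mapping[int, GroundTruthEntry] | None = None,
) -> list[tuple[float, float]]:
    """(position, apex weight) of every line a metabolite occupies.

    If the metabolite is present in the supplied ground truth, the actually
    rendered (jittered) lines and amplitudes are returned; otherwise the
    library positions are laid out with the same deterministic pattern
    generator at unit amplitude.
    """
    if ground_truth is not None:
        hits = [e for e in ground_truth.values() if e.metabolite == metabolite]
        if hits:
            return [
                (p, w)
                for e in hits
                for p, w in zip(e.line_positions, e.line_weights)
            ]
    if metabolite not in lib.metabolites:
        raise LibraryError(f"unknown metabolite {metabolite!r}")
    out: list[tuple[float, float]] = []
    for sig in lib.metabolites[metabolite]:
        out.extend(simulate_multiplet(sig, 1.0, params))
    return out


def expected_line_positions(
    lib: ReferenceLibrary,
    metabolite: str,
    params: SimulationParams,
    ground_truth: Mapping[int, GroundTruthEntry] | None = None,
) -> list[float]:
    """Line positions a metabolite occupies (or would occupy) in a spectrum."""
    return [p for p, _ in expected_lines(lib, metabolite, params, ground_truth)]


def simulate_spike(
    base: Spectrum1D,
    ground_truth: Mapping[int, GroundTruthEntry],
    lib: ReferenceLibrary,
    metabolite: str,
    fold_increase: float,
    params: SimulationParams,
    present: bool | None = None,
) -> Spectrum1D:
    """Re-acquisition after standard addition of one pure compound.

    If the compound is present in the base mixture its existing lines scale by
    ``fold_increase``; if absent, its library lines appear at new positions
    (the sarcosine situation).
    """
    if metabolite not in lib.metabolites:
        raise LibraryError(f"unknown metabolite {metabolite!r}")
    in_truth = any(e.metabolite == metabolite for e in ground_truth.values())
    if present is None:
        present = in_truth
    out = base.copy()
    if present and in_truth:
        for e in ground_truth.values():
            if e.metabolite != metabolite:
                continue
            fwhm = params.fwhm_total_hz * (6.0 if e.multiplicity == "br" else 1.0)
            out.intensities += _render(
                out.ppm,
                e.line_positions,
                [(fold_increase - 1.0) * w for w in e.line_weights],
                fwhm,
                params,
            )
    else:
        for sig in lib.metabolites[metabolite]:
            centre, positions, apexes, fwhm, _ = _layout(sig, 1.0, params)
            out.intensities += _render(out.ppm, positions, apexes, fwhm, params)
    return out


def demo_amplitudes(lib: ReferenceLibrary) -> dict[str, float]:
    """The full-evidence demonstration mixture: every catalogued metabolite.

    Dominance of the resting-period metabolome (putrescine, trimethylamine,
    succinate, betaine) is honoured qualitatively with larger amplitudes.
    Spike standards (level ``unknown``) are excluded - they are below the
    detection limit of the reference mixture by construction.
    """
    dominant = {
        "Putrescine": 6.0,
        "Trimethylamine": 6.0,
        "Succinic acid": 5.0,
        "Betaine": 5.0,
    }
    out: dict[str, float] = {}
    for name, sigs in lib.metabolites.items():
        if sigs[0].confidence_level == "unknown":
            continue
        out[name] = dominant.get(name, 1.0)
    return out
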