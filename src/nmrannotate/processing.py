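"""1D spectrum reading: referencing, peak picking and multiplet grouping.

This is the pipeline's stand-in for reading the 1D trace together with the
J-resolved projection: translate the axis so TSP sits at 0 ppm, detect peak
apexes, and merge runs of near-equally spaced peaks into classified multiplets
(s/d/t/q by binomial intensity ratios, dd by the symmetric four-line pattern,
everything else an unresolved ``m``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.signal import find_peaks

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .simulate import Spectrum1D

__all__ = [
    "Peak",
    "Multiplet",
    "ReferencingError",
    "reference_to_tsp",
    "estimate_noise",
    "pick_peaks",
    "group_multiplets",
]


class ReferencingError(RuntimeError):
    """No TSP candidate found in the search window."""


@dataclass(frozen=True)
class Peak:
    """A single detected line: apex position (ppm), intensity, width (Hz)."""

    position: float
    intensity: float
    fwhm_hz: float = 0.0


@dataclass
class Multiplet:
    """A group of peaks belonging to one nucleus's signal."""

    signal_id: int
    centre: float  # ppm
    multiplicity: str  # s/d/t/q/dd/qd/m/br
    n_peaks: int | None = None  # observed peak count where the label is "m"
    j_est: float | None = None  # Hz
    peaks: list[Peak] = field(default_factory=list)
    area: float = 0.0
    unclassifiable: bool = False

    @property
    def observed_count(self) -> int | None:
        if self.n_peaks is not None:
            return self.n_peaks
        if self.peaks:
            return len(self.peaks)
        return None

    def span(self) -> tuple[float, float]:
        """(upfield, downfield) extremes of the member lines, ppm."""
        pos = [p.position for p in self.peaks] or [self.centre]
        return min(pos), max(pos)


def reference_to_tsp(spec: "Spectrum1D", search_window: float = 0.3) -> "Spectrum1D":
    """Translate the axis so the TSP apex sits exactly at 0 ppm.

    Idempotent: referencing an already-referenced spectrum leaves it
    unchanged (up to the apex-refinement resolution).
    """
    mask = np.abs(spec.ppm) <= search_window
    if not mask.any() or np.all(spec.intensities[mask] <= 0):
        raise ReferencingError("reference not found: no TSP candidate near 0 ppm")
    idx = np.flatnonzero(mask)
    apex_rel = int(np.argmax(spec.intensities[idx]))
    apex = idx[apex_rel]
    offset = _parabolic_apex(spec.ppm, spec.intensities, apex)
    out = spec.copy()
    out.ppm = out.ppm - offset
    out.referenced = True
    return out


def _parabolic_apex(ppm: np.ndarray, y: np.ndarray, i: int) -> float:
    """3-point parabolic refinement of the apex position at index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(ppm[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(ppm[i])
    delta = 0.5 * (y0 - y2) / denom
    step = ppm[i + 1] - ppm[i]  # negative on a descending axis
    return float(ppm[i] + delta * step)


def estimate_noise(
    spec: "Spectrum1D", region: tuple[float, float] = (9.5, 10.0)
) -> float:
    """Robust noise sigma: 1.4826 x MAD over a signal-free region."""
    lo, hi = min(region), max(region)
    mask = (spec.ppm >= lo) & (spec.ppm <= hi)
    vals = spec.intensities[mask]
    if vals.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(vals - np.median(vals))))


def pick_peaks(
    spec: "Spectrum1D",
    snr_threshold: float = 5.0,
    noise_region: tuple[float, float] = (9.5, 10.0),
    tsp_exclusion: float = 0.2,
) -> list[Peak]:
    """Local maxima above ``snr_threshold`` times the robust noise estimate.

    Apexes are refined by 3-point parabolic interpolation; the TSP region
    around 0 ppm is excluded.  On a noiseless spectrum a small floor relative
    to the global maximum stands in for the noise estimate.
    """
    if not spec.referenced:
        raise ValueError("peak picking requires a referenced spectrum")
    y = spec.intensities
    top = float(np.max(y)) if len(y) else 0.0
    if top <= 0:
        return []
    sigma = estimate_noise(spec, noise_region)
    floor = max(snr_threshold * sigma, 1e-6 * top)
    idx, _ = find_peaks(y, height=floor)
    out: list[Peak] = []
    step_hz = spec.params.grid_step * spec.params.spectrometer_freq
    for i in idx:
        pos = _parabolic_apex(spec.ppm, y, int(i))
        if abs(pos) <= tsp_exclusion:
            continue
        half = y[i] / 2.0
        left = i
        while left > 0 and y[left] > half:
            left -= 1
        right = i
        while right < len(y) - 1 and y[right] > half:
            right += 1
        fwhm = (right - left) * step_hz
        out.append(Peak(position=pos, intensity=float(y[i]), fwhm_hz=fwhm))
    out.sort(key=lambda p: p.position)
    return out


def _binomial_ok(intensities: Sequence[float], pattern: Sequence[int], tol: float) -> bool:
    w = np.asarray(intensities, dtype=float)
    ref = np.asarray(pattern, dtype=float)
    w = w / w.max()
    ref = ref / ref.max()
    return bool(np.all(np.abs(w - ref) <= tol * ref))


def _classify(run: list[Peak], j_tol_hz: float, int_tol: float, freq: float) -> tuple[str, float | None]:
    """Multiplicity label and J estimate for a run of consecutive peaks."""
    n = len(run)
    if n == 1:
        return "s", None
    pos = np.array([p.position for p in run])
    inten = [p.intensity for p in run]
    gaps_hz = np.diff(pos) * freq
    equal = np.all(np.abs(gaps_hz - gaps_hz.mean()) <= j_tol_hz)
    if equal:
        j = float(gaps_hz.mean())
        if n == 2 and _binomial_ok(inten, (1, 1), int_tol):
            return "d", j
        if n == 3 and _binomial_ok(inten, (1, 2, 1), int_tol):
            return "t", j
        if n == 4 and _binomial_ok(inten, (1, 3, 3, 1), int_tol):
            return "q", j
    elif n == 4:
        # doublet of doublets: symmetric a, b, a spacing, near-equal intensities
        a1, b, a2 = gaps_hz
        if abs(a1 - a2) <= j_tol_hz and _binomial_ok(inten, (1, 1, 1, 1), int_tol):
            return "dd", float((a1 + a2) / 2.0)
    return "m", None


def group_multiplets(
    peaks: Sequence[Peak],
    j_tolerance: float = 0.3,  # Hz, spacing agreement
    intensity_tolerance: float = 0.25,  # fractional deviation from binomial
    spectrometer_freq: float = 600.0,
    max_j_hz: float = 20.0,  # JRES F1 window: couplings beyond this split runs
) -> list[Multiplet]:
    """Merge runs of near-equally spaced peaks into classified multiplets.

    Peaks further apart than ``max_j_hz`` never join one multiplet.  A peak
    that could extend either of two adjacent patterns goes to the one that
    minimizes the total spacing variance.  Every peak belongs to exactly one
    multiplet (worst case: a singlet of its own).
    """
    peaks = sorted(peaks, key=lambda p: p.position)
    clusters: list[list[Peak]] = []
    for p in peaks:
        if (
            clusters
            and (p.position - clusters[-1][-1].position) * spectrometer_freq <= max_j_hz
        ):
            clusters.append(clusters[-1] + [p])
            clusters.pop(-2)
        else:
            clusters.append([p])
    out: list[Multiplet] = []
    for cluster in clusters:
        out.extend(
            _split_cluster(cluster, j_tolerance, intensity_tolerance, spectrometer_freq)
        )
    # downfield-first signal ids, as annotation reports are read
    out.sort(key=lambda m: -m.centre)
    for sid, m in enumerate(out, start=1):
        m.signal_id = sid
    return out


def _make_multiplet(run: list[Peak], j_tol: float, int_tol: float, freq: float) -> Multiplet:
    mult, j = _classify(run, j_tol, int_tol, freq)
    weights = np.array([p.intensity for p in run])
    pos = np.array([p.position for p in run])
    centre = float(np.average(pos, weights=weights))
    area = float(
        sum(p.intensity * np.pi * (p.fwhm_hz / 2.0) / freq for p in run)
    )
    return Multiplet(
        signal_id=0,
        centre=centre,
        multiplicity=mult,
        n_peaks=len(run) if mult == "m" else None,
        j_est=j,
        peaks=list(run),
        area=area,
        unclassifiable=(mult == "m"),
    )


_MIN_J_HZ = 1.5  # couplings below this are unresolvable at ~1.3 Hz linewidth


def _classifiable_end(
    cluster: list[Peak], i: int, j_tol: float, int_tol: float, freq: float
) -> int | None:
    """End index of the longest classifiable run starting at ``i``, if any.

    Longest-first so a quartet is not consumed as two doublets; a bare singlet
    only counts as classifiable when it is resolved from its neighbour (gap at
    least the minimum resolvable coupling), otherwise it belongs to an
    unresolved cluster.  When a peak could extend two patterns the longer,
    lower-spacing-variance reading wins, which is what longest-first plus the
    spacing-agreement tolerance implements.
    """
    n = len(cluster)
    for end in range(min(n, i + 8), i + 1, -1):
        run = cluster[i:end]
        gaps = np.diff([p.position for p in run]) * freq
        if np.any(gaps < _MIN_J_HZ):
            continue
        mult, _ = _classify(run, j_tol, int_tol, freq)
        if mult != "m":
            return end
    gap_prev = (
        (cluster[i].position - cluster[i - 1].position) * freq if i > 0 else np.inf
    )
    gap_next = (
        (cluster[i + 1].position - cluster[i].position) * freq if i + 1 < n else np.inf
    )
    if gap_prev >= _MIN_J_HZ and gap_next >= _MIN_J_HZ:
        return i + 1  # resolved singlet
    return None


def _split_cluster(
    cluster: list[Peak], j_tol: float, int_tol: float, freq: float
) -> list[Multiplet]:
    """Segment a gap-connected peak cluster into multiplets.

    Classifiable runs (s/d/t/q/dd) are emitted as such; stretches where no
    pattern fits are emitted as a single unresolved ``m`` multiplet.
    """
    # a gap below the resolvable-coupling floor means foreign lines interleave:
    # the whole cluster is one unresolved signal (the 1D trace cannot separate
    # coincident multiplets; only the J dimension can)
    gaps = np.diff([p.position for p in cluster]) * freq
    if len(cluster) > 1 and np.any(gaps < _MIN_J_HZ):
        return [_make_multiplet(cluster, j_tol, int_tol, freq)]
    out: list[Multiplet] = []
    i = 0
    n = len(cluster)
    while i < n:
        end = _classifiable_end(cluster, i, j_tol, int_tol, freq)
        if end is not None:
            out.append(_make_multiplet(cluster[i:end], j_tol, int_tol, freq))
            i = end
        else:
            j = i + 1
            while j < n and _classifiable_end(cluster, j, j_tol, int_tol, freq) is None:
                j += 1
            out.append(_make_multiplet(cluster[i:j], j_tol, int_tol, freq))
            i = j
    return out
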