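"""Spectral bucketing: uniform bins, peak-aligned buckets, metabolite merging.

Bucketing turns a spectrum into the variable table multivariate statistics
consume.  Uniform bucketing slices a window into equal parts; intelligent
bucketing aligns one bucket to each multiplet so a bucket carries chemical
meaning; merging sums the buckets of a single annotated metabolite into one
feature (ideally one variable per metabolite), writing the bucket-metabolite
association table alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import Annotation
from .processing import Multiplet
from .simulate import Spectrum1D

__all__ = [
    "Bucket",
    "uniform_buckets",
    "intelligent_buckets",
    "merge_buckets",
]


@dataclass
class Bucket:
    """An integration window on the descending ppm axis (right < left)."""

    left: float  # downfield bound, ppm
    right: float  # upfield bound, ppm
    intensity: float = 0.0
    signal_id: int | None = None

    def __post_init__(self) -> None:
        if not self.right < self.left:
            raise ValueError("bucket bounds must satisfy right < left")

    @property
    def width(self) -> float:
        return self.left - self.right

    @property
    def centre(self) -> float:
        return 0.5 * (self.left + self.right)


def _integrate(spec: Spectrum1D, left: float, right: float) -> float:
    """Trapezoidal integral over [right, left] ppm with exact-bound endpoints.

    Endpoint intensities are interpolated at the bucket bounds so adjacent
    buckets telescope: the sum of contiguous buckets equals the integral over
    their union.
    """
    x = spec.ppm[::-1]  # ascending view
    y = spec.intensities[::-1]
    lo, hi = max(right, x[0]), min(left, x[-1])
    if hi <= lo:
        return 0.0
    inner = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inner], [hi]))
    ys = np.concatenate(([np.interp(lo, x, y)], y[inner], [np.interp(hi, x, y)]))
    return float(np.trapezoid(ys, xs))


def uniform_buckets(
    spec: Spectrum1D,
    width: float,
    window: tuple[float, float] = (0.5, 10.0),
    exclusions: Sequence[tuple[float, float]] = ((4.7, 4.9),),
) -> list[Bucket]:
    """Contiguous equal-width buckets over the window, downfield first.

    Buckets overlapping an exclusion band (residual water by default) are
    dropped.  The sum of bucket intensities equals the integral of the
    spectrum over the retained windows.
    """
    if width <= 0:
        raise ValueError("bucket width must be positive")
    lo, hi = min(window), max(window)
    n = int(round((hi - lo) / width))
    out: list[Bucket] = []
    for k in range(n):
        left = hi - k * width
        right = left - width
        if any(r_lo < left and right < r_hi for r_lo, r_hi in exclusions):
            continue
        out.append(Bucket(left=left, right=right, intensity=_integrate(spec, left, right)))
    return out


def intelligent_buckets(
    spec: Spectrum1D,
    multiplets: Sequence[Multiplet],
    pad_fwhm: float = 2.0,
) -> list[Bucket]:
    """One bucket per multiplet, spanning its outermost peaks +/- pad x FWHM.

    The boundary between two overlapping adjacent buckets is placed at the
    intensity minimum between the neighbouring outer lines, with a warning.
    Each bucket keeps the multiplet's signal id so annotation-aware merging
    can follow.
    """
    if not multiplets:
        return []
    freq = spec.params.spectrometer_freq
    step = spec.params.grid_step
    ordered = sorted(multiplets, key=lambda m: -m.centre)
    # physically coincident multiplets (centres within one grid step) cannot
    # be separated by any boundary: they share one bucket
    groups: list[list] = []
    for m in ordered:
        if groups and abs(groups[-1][-1].centre - m.centre) <= step:
            groups[-1].append(m)
            warnings.warn(
                f"coincident multiplets near {m.centre:.3f} ppm share one bucket",
                stacklevel=2,
            )
        else:
            groups.append([m])

    desired = []  # [left, right, signal_id, centre]
    for grp in groups:
        lines_up = min(m.span()[0] for m in grp)
        lines_down = max(m.span()[1] for m in grp)
        fwhm_hz = max(
            (p.fwhm_hz for m in grp for p in m.peaks),
            default=spec.params.fwhm_total_hz,
        )
        pad = pad_fwhm * max(fwhm_hz, spec.params.fwhm_total_hz) / freq
        centre = float(np.mean([m.centre for m in grp]))
        desired.append([lines_down + pad, lines_up - pad, grp[0].signal_id, centre])

    def _minimum_between(hi: float, lo: float) -> float:
        mask = (spec.ppm < hi) & (spec.ppm > lo)
        if not mask.any():
            return 0.5 * (hi + lo)
        sub = np.flatnonzero(mask)
        return float(spec.ppm[sub[np.argmin(spec.intensities[sub])]])

    # a boundary strictly between consecutive centres keeps every bucket
    # non-degenerate even when a narrow signal is nested inside a wide
    # neighbour's span
    out: list[Bucket] = []
    for i, (left, right, sid, centre) in enumerate(desired):
        if i > 0:
            prev_left, prev_right, _, prev_centre = desired[i - 1]
            if left > prev_right:  # spans overlap on the descending axis
                boundary = _minimum_between(left, prev_right)
                # nested spans: keep each bucket around its own centre
                boundary = min(max(boundary, centre + step), prev_centre - step)
                warnings.warn(
                    f"overlapping multiplet buckets near {boundary:.3f} ppm; "
                    "shared boundary placed at the intensity minimum",
                    stacklevel=2,
                )
                left = boundary
                desired[i - 1][1] = boundary
        desired[i][0] = left
    for left, right, sid, centre in desired:
        left = max(left, centre + step / 2)
        right = min(right, centre - step / 2)
        out.append(
            Bucket(left=left, right=right, intensity=_integrate(spec, left, right),
                   signal_id=sid)
        )
    return out


def merge_buckets(
    buckets: Sequence[Bucket],
    annotations: Sequence[Annotation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum buckets of one metabolite into a single feature.

    Returns ``(features, association)``: the feature table (one row per
    metabolite or per pass-through bucket) and the bucket-metabolite
    association table.  Total intensity is conserved.
    """
    sid_to_name: dict[int, str] = {}
    for ann in annotations:
        if ann.assigned_name is None:
            continue
        for sid in ann.system.member_ids:
            sid_to_name[sid] = ann.assigned_name
    feat: dict[str, float] = {}
    order: list[str] = []
    assoc_rows = []
    for b in buckets:
        name = sid_to_name.get(b.signal_id) if b.signal_id is not None else None
        label = name if name is not None else f"bucket_{b.left:.4f}_{b.right:.4f}"
        if label not in feat:
            feat[label] = 0.0
            order.append(label)
        feat[label] += b.intensity
        assoc_rows.append(
            {
                "bucket_left": b.left,
                "bucket_right": b.right,
                "metabolite": name if name is not None else "",
            }
        )
    features = pd.DataFrame(
        {"feature": order, "intensity": [feat[k] for k in order]}
    )
    association = pd.DataFrame(
        assoc_rows, columns=["bucket_left", "bucket_right", "metabolite"]
    )
    return features, association
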