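"""JCAMP-DX spectrum I/O (AFFN writing; AFFN and PAC reading).

The annotated spectrum travels as JCAMP-DX, the open interchange format every
NMR package reads.  Writing sticks to plain-number AFFN encoding so the file
stays bit-auditable; reading accepts AFFN and PAC.  Compressed dialects
(SQZ/DIF/DUP) are refused with an explicit error naming the dialect - they
are not part of this artifact's surface.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import SimulationParams, Spectrum1D

__all__ = ["read_jcampdx", "write_jcampdx", "JcampError"]


class JcampError(ValueError):
    pass


_SQZ_DIGITS = "@ABCDEFGHIabcdefghi"
_DIF_DIGITS = "%JKLMNOPQRjklmnopqr"
_DUP_DIGITS = "STUVWXYZs"


def write_jcampdx(
    spec: Spectrum1D,
    path: str | Path,
    title: str = "nmrannotate simulated spectrum",
    comments: Sequence[str] = (),
    peak_annotations: Sequence[tuple[float, float, str]] = (),
) -> None:
    """Write a spectrum as JCAMP-DX 4.24 with AFFN XYDATA.

    Intensities are quantized by YFACTOR (31-bit integer range); optional
    peak annotations are embedded as a ##PEAK TABLE=(XYA) block so viewers
    can render assignment labels directly on the spectrum.
    """
    path = Path(path)
    y = spec.intensities
    maxy = float(np.max(np.abs(y))) if len(y) else 1.0
    yfactor = maxy / 2147483000.0 if maxy > 0 else 1.0
    iy = np.round(y / yfactor).astype(np.int64)
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##DATA CLASS=XYDATA",
        f"##.OBSERVE FREQUENCY={spec.params.spectrometer_freq}",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##FIRSTX={spec.ppm[0]:.10g}",
        f"##LASTX={spec.ppm[-1]:.10g}",
        f"##NPOINTS={len(y)}",
        "##XFACTOR=1.0",
        f"##YFACTOR={yfactor:.12e}",
        f"##FIRSTY={y[0]:.10g}",
        f"##MAXY={float(np.max(y)):.10g}" if len(y) else "##MAXY=0",
        f"##MINY={float(np.min(y)):.10g}" if len(y) else "##MINY=0",
    ]
    for c in comments:
        lines.append(f"$$ {c}")
    lines.append("##XYDATA=(X++(Y..Y))")
    step = (spec.ppm[-1] - spec.ppm[0]) / (len(y) - 1) if len(y) > 1 else 0.0
    per_row = 8
    for i in range(0, len(iy), per_row):
        x = spec.ppm[0] + i * step
        row = " ".join(str(int(v)) for v in iy[i : i + per_row])
        lines.append(f"{x:.6f} {row}")
    if peak_annotations:
        lines.append("$$ peak annotations: position ppm, intensity, label")
        lines.append(f"##PEAK TABLE=(XYA), PEAKS={len(peak_annotations)}")
        for pos, inten, label in peak_annotations:
            lines.append(f"{pos:.4f}, {inten:.6g}, <{label}>")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _check_dialect(token: str) -> None:
    for ch in token:
        if ch in _SQZ_DIGITS:
            raise JcampError("unsupported compression dialect: SQZ")
        if ch in _DIF_DIGITS:
            raise JcampError("unsupported compression dialect: DIF")
        if ch in _DUP_DIGITS:
            raise JcampError("unsupported compression dialect: DUP")


_NUM_RE = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def read_jcampdx(path: str | Path, params: SimulationParams | None = None) -> Spectrum1D:
    """Read an AFFN/PAC JCAMP-DX file back into a spectrum.

    The ppm axis is reconstructed from FIRSTX/LASTX/NPOINTS and intensities
    scaled by YFACTOR.  NPOINTS mismatching the data stream is an error.
    """
    path = Path(path)
    headers: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
                continue
            if key in ("END", "PEAK TABLE"):
                in_data = False
            headers[key] = val.strip()
            continue
        if in_data:
            _check_dialect(line)
            nums = _NUM_RE.findall(line.replace(",", " "))
            if not nums:
                continue
            ys.extend(float(v) for v in nums[1:])  # first token is the X value
    for req in ("TITLE",):
        if req not in headers:
            raise JcampError(f"missing ##{req} record")
    if "FIRSTX" not in headers or "LASTX" not in headers or "NPOINTS" not in headers:
        raise JcampError("missing FIRSTX/LASTX/NPOINTS records")
    n = int(headers["NPOINTS"])
    if n != len(ys):
        raise JcampError(f"NPOINTS={n} but {len(ys)} intensity values present")
    firstx = float(headers["FIRSTX"])
    lastx = float(headers["LASTX"])
    yfactor = float(headers.get("YFACTOR", "1.0"))
    ppm = np.linspace(firstx, lastx, n)
    y = np.asarray(ys, dtype=float) * yfactor
    if params is None:
        freq = float(headers.get(".OBSERVE FREQUENCY", "600.0"))
        params = SimulationParams(
            spectrometer_freq=freq,
            spectral_width=abs(firstx - lastx),
            n_points=n,
            axis_max=max(firstx, lastx),
        )
    return Spectrum1D(ppm, y, params, referenced=True)
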