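"""Reference signal library: the printed whole-body metabolite catalogue.

The library is the single source of truth for the whole pipeline: the
simulator renders spectra from it, the annotation engine matches against it,
and the confidence tabulations are computed from it.  Each row of the packaged
file is one ``ReferenceSignal``; a metabolite is the group of rows sharing a
``metabolite_name``.

Confidence levels follow the MSI-adapted scale used for the catalogue:
``1`` (identified, spike-confirmed), ``2+`` (putative, several 2D
confirmations), ``2-`` (putative, at most one confirmation or a poorly
referenced compound), ``3`` (compound class only) and ``unknown`` (spike
standards that were never detected in the reference mixture).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ReferenceSignal",
    "ReferenceLibrary",
    "LibraryError",
    "load_library",
    "write_library",
    "packaged_library_path",
    "load_packaged_library",
    "tabulate_confidence",
    "default_j",
    "implied_peak_count",
]

#: multiplicity codes of the catalogue; ``m`` may carry an observed peak count
MULTIPLICITIES = ("s", "d", "t", "q", "dd", "qd", "m", "br")
CONFIDENCE_LEVELS = ("1", "2+", "2-", "3", "unknown")
COMPOUND_CLASSES = (
    "proteinogenic amino acid",
    "amine/amide-osmolyte",
    "carboxylic acid",
    "nucleotide-nucleoside",
    "coenzyme",
    "carbohydrate",
    "unknown",
)

#: number of lines of a first-order pattern
_IMPLIED_COUNT = {"s": 1, "d": 2, "t": 3, "q": 4, "dd": 4, "qd": 8, "br": 1}

_COLUMNS = [
    "metabolite",
    "class",
    "shift_ppm",
    "multiplicity",
    "n_peaks",
    "j_hz",
    "c13_ppm",
    "p31",
    "level",
    "spiked",
    "poorly_referenced",
    "spin_group",
    "class_hint",
    "range_lo",
    "range_hi",
    "p31_ppm",
]


class LibraryError(ValueError):
    """Raised on malformed or inconsistent library files."""


@dataclass(frozen=True)
class ReferenceSignal:
    """One catalogued 1H signal of a metabolite."""

    metabolite_name: str
    compound_class: str
    shift_h1: float
    multiplicity: str
    n_peaks: int | None = None
    j_values: tuple[float, ...] = ()
    shift_c13: float | None = None
    has_p31_correlation: bool = False
    p31_shift: float | None = None
    confidence_level: str = "unknown"
    spiked: bool = False
    poorly_referenced: bool = False
    spin_group: str = "g1"
    class_hint: str = ""
    shift_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.multiplicity not in MULTIPLICITIES:
            raise LibraryError(
                f"unknown multiplicity {self.multiplicity!r} for "
                f"{self.metabolite_name} at {self.shift_h1} ppm"
            )
        if self.confidence_level not in CONFIDENCE_LEVELS:
            raise LibraryError(
                f"unknown confidence level {self.confidence_level!r}"
            )
        if self.compound_class not in COMPOUND_CLASSES:
            raise LibraryError(
                f"unknown compound class {self.compound_class!r}"
            )
        if not (-0.5 <= self.shift_h1 <= 10.5):
            raise LibraryError(
                f"shift {self.shift_h1} ppm outside [-0.5, 10.5] for "
                f"{self.metabolite_name}"
            )

    @property
    def effective_j(self) -> tuple[float, ...]:
        """Coupling constants: explicit values or the deterministic defaults."""
        if self.j_values:
            return self.j_values
        return default_j(self.multiplicity, self.shift_h1)

    @property
    def expected_peak_count(self) -> int | None:
        if self.n_peaks is not None:
            return self.n_peaks
        return _IMPLIED_COUNT.get(self.multiplicity)


def implied_peak_count(multiplicity: str) -> int | None:
    """Line count implied by a resolved multiplicity letter (None for m)."""
    return _IMPLIED_COUNT.get(multiplicity)


def default_j(multiplicity: str, shift_ppm: float) -> tuple[float, ...]:
    """First-order default coupling constants in Hz.

    The catalogue prints no J values, so the library applies literature-typical
    defaults chosen by region: aromatic couplings 8.0 Hz above 6 ppm, anomeric
    couplings 3.8 Hz (alpha, 4.9-5.6 ppm) or 8.0 Hz (beta, 4.4-4.9 ppm),
    aliphatic 7.0 Hz elsewhere.  The rule is deterministic so the simulator and
    the matcher always agree.
    """
    if multiplicity in ("s", "br"):
        return ()
    if multiplicity == "dd":
        return (16.0, 6.0)
    if multiplicity == "qd":
        return (7.0, 1.8)
    if shift_ppm > 6.0:
        base = 8.0
    elif 4.9 <= shift_ppm <= 5.6:
        base = 3.8
    elif 4.4 <= shift_ppm < 4.9:
        base = 8.0
    else:
        base = 7.0
    if multiplicity == "m":
        return (base,)
    return (base,)


@dataclass
class ReferenceLibrary:
    """The full signal catalogue with its metabolite-level grouping."""

    signals: list[ReferenceSignal]
    provenance: str = ""

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        seen: set[tuple[str, float]] = set()
        for sig in self.signals:
            key = (sig.metabolite_name, sig.shift_h1)
            if key in seen:
                raise LibraryError(
                    f"duplicate (metabolite, shift) pair {key}"
                )
            seen.add(key)
            if sig.confidence_level == "1" and not sig.spiked:
                raise LibraryError(
                    f"level-1 signal of {sig.metabolite_name} not spiked"
                )
        for name, sigs in self.metabolites.items():
            levels = {s.confidence_level for s in sigs}
            if len(levels) != 1:
                raise LibraryError(
                    f"non-uniform confidence level for {name}: {levels}"
                )
            classes = {s.compound_class for s in sigs}
            if len(classes) != 1:
                raise LibraryError(
                    f"metabolite {name} spans classes {classes}"
                )

    @property
    def metabolites(self) -> dict[str, list[ReferenceSignal]]:
        out: dict[str, list[ReferenceSignal]] = {}
        for sig in self.signals:
            out.setdefault(sig.metabolite_name, []).append(sig)
        return out

    def metabolite_level(self, name: str) -> str:
        return self.metabolites[name][0].confidence_level

    def metabolite_class(self, name: str) -> str:
        return self.metabolites[name][0].compound_class

    def is_database_reference(self, name: str) -> bool:
        """Whether this record acts as a database entry during matching.

        Level-3 records are class-only (no metabolite name to match); spike
        standards at level ``unknown`` are legitimate database compounds (the
        sarcosine situation) and do participate.
        """
        return self.metabolite_level(name) != "3"

    def subset(self, names: Iterable[str]) -> "ReferenceLibrary":
        names = set(names)
        missing = names - set(self.metabolites)
        if missing:
            raise LibraryError(f"metabolites not in library: {sorted(missing)}")
        return ReferenceLibrary(
            [s for s in self.signals if s.metabolite_name in names],
            provenance=self.provenance,
        )

    def checksum(self) -> str:
        h = hashlib.sha256()
        for sig in self.signals:
            h.update(repr(sig).encode())
        return h.hexdigest()[:12]


def _parse_bool(tok: str) -> bool:
    return tok.strip() in ("1", "true", "True", "yes")


def _parse_float(tok: str) -> float | None:
    tok = tok.strip()
    return float(tok) if tok else None


def load_library(path: str | Path) -> ReferenceLibrary:
    """Parse a delimiter-separated library file.

    Raises :class:`LibraryError` naming the offending line for malformed rows,
    and refuses empty files (an empty catalogue is never a valid library).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    signals: list[ReferenceSignal] = []
    header: list[str] | None = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            if header[: len(_COLUMNS)] != _COLUMNS[: len(header)]:
                raise LibraryError(
                    f"{path}:{lineno}: unexpected column header {header!r}"
                )
            continue
        # right-pad optional trailing columns
        fields = fields + [""] * (len(_COLUMNS) - len(fields))
        if len(fields) > len(_COLUMNS):
            raise LibraryError(f"{path}:{lineno}: too many columns")
        row = dict(zip(_COLUMNS, fields))
        try:
            n_peaks = row["n_peaks"].strip()
            j_hz = row["j_hz"].strip()
            lo = _parse_float(row["range_lo"])
            hi = _parse_float(row["range_hi"])
            sig = ReferenceSignal(
                metabolite_name=row["metabolite"].strip(),
                compound_class=row["class"].strip(),
                shift_h1=float(row["shift_ppm"]),
                multiplicity=row["multiplicity"].strip(),
                n_peaks=int(n_peaks) if n_peaks else None,
                j_values=tuple(float(j) for j in j_hz.split(",")) if j_hz else (),
                shift_c13=_parse_float(row["c13_ppm"]),
                has_p31_correlation=_parse_bool(row["p31"]),
                p31_shift=_parse_float(row["p31_ppm"]),
                confidence_level=row["level"].strip(),
                spiked=_parse_bool(row["spiked"]),
                poorly_referenced=_parse_bool(row["poorly_referenced"]),
                spin_group=row["spin_group"].strip() or "g1",
                class_hint=row["class_hint"].strip(),
                shift_range=(lo, hi) if lo is not None and hi is not None else None,
            )
        except (ValueError, KeyError) as exc:
            raise LibraryError(f"{path}:{lineno}: malformed row ({exc})") from exc
        signals.append(sig)
    if not signals:
        raise LibraryError(f"{path}: no signal rows found")
    return ReferenceLibrary(signals, provenance=str(path))


def write_library(lib: ReferenceLibrary, path: str | Path) -> None:
    """Serialize a library; ``load_library(write_library(lib))`` is lossless."""
    path = Path(path)
    rows = ["# nmrannotate reference signal library\tformat_version=1"]
    rows.append("\t".join(_COLUMNS))
    for s in lib.signals:
        rows.append(
            "\t".join(
                [
                    s.metabolite_name,
                    s.compound_class,
                    repr(s.shift_h1),
                    s.multiplicity,
                    "" if s.n_peaks is None else str(s.n_peaks),
                    ",".join(repr(j) for j in s.j_values),
                    "" if s.shift_c13 is None else repr(s.shift_c13),
                    "1" if s.has_p31_correlation else "0",
                    s.confidence_level,
                    "1" if s.spiked else "0",
                    "1" if s.poorly_referenced else "0",
                    s.spin_group,
                    s.class_hint,
                    "" if s.shift_range is None else repr(s.shift_range[0]),
                    "" if s.shift_range is None else repr(s.shift_range[1]),
                    "" if s.p31_shift is None else repr(s.p31_shift),
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def packaged_library_path() -> Path:
    return Path(__file__).parent / "data" / "reference_library.tsv"


def load_packaged_library() -> ReferenceLibrary:
    return load_library(packaged_library_path())


def tabulate_confidence(lib: ReferenceLibrary) -> pd.DataFrame:
    """Metabolite counts by confidence level and compound class.

    Returns a table with one row per (level, class) pair plus the per-level
    totals the catalogue's summary quotes: level-1 metabolites were confirmed
    by spiking, level-1 plus level-2+ form the "identified" total.
    """
    records = []
    for name, sigs in lib.metabolites.items():
        records.append(
            {
                "metabolite": name,
                "level": sigs[0].confidence_level,
                "class": sigs[0].compound_class,
            }
        )
    df = pd.DataFrame(records, columns=["metabolite", "level", "class"])
    if df.empty:
        counts = pd.DataFrame(columns=["level", "class", "n"])
    else:
        counts = (
            df.groupby(["level", "class"], as_index=False)
            .size()
            .rename(columns={"size": "n"})
        )
    return counts


def confidence_summary(lib: ReferenceLibrary) -> Mapping[str, int]:
    """Headline counts: metabolites per level and the identified total."""
    levels = [sigs[0].confidence_level for sigs in lib.metabolites.values()]
    out = {lvl: levels.count(lvl) for lvl in CONFIDENCE_LEVELS}
    out["identified"] = out["1"] + out["2+"]
    out["total"] = len(levels)
    return out


def class_counts_identified(lib: ReferenceLibrary) -> dict[str, int]:
    """Compound-class counts restricted to levels 1 and 2+."""
    out: dict[str, int] = {}
    for name, sigs in lib.metabolites.items():
        if sigs[0].confidence_level in ("1", "2+"):
            cls = sigs[0].compound_class
            out[cls] = out.get(cls, 0) + 1
    return out
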