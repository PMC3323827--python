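"""Core domain objects: mass spectra, peaks and per-run peak tables.

A GCxGC/TOF-MS experiment output ("run") is represented as a
:class:`PeakTable` holding one :class:`Peak` per detected chromatographic
peak. Each peak carries two retention times (first-dimension RT in minutes,
second-dimension RT in seconds), a peak area, an optional compound
identification key and a centroided mass :class:`Spectrum`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

from .errors import InvalidSpectrumError, SpectrumParseError, FormatError

__all__ = ["Spectrum", "Peak", "PeakTable", "parse_spectrum", "resolve_compound_key"]


@dataclass(frozen=True)
class Spectrum:
    """A centroided mass spectrum: strictly increasing m/z with intensities.

    Parameters
    ----------
    mz : array of float
        Mass-to-charge values, unique and strictly increasing.
    intensity : array of float
        Nonnegative abundances (arbitrary units); at least one must be > 0.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.shape != mz.shape or mz.size == 0:
            raise InvalidSpectrumError("spectrum needs matching 1-D mz/intensity arrays")
        if not np.all(np.diff(mz) > 0):
            raise InvalidSpectrumError("mz values must be unique and strictly increasing")
        if not np.all(np.isfinite(inten)) or np.any(inten < 0):
            raise InvalidSpectrumError("intensities must be finite and nonnegative")
        if not np.any(inten > 0):
            raise InvalidSpectrumError("spectrum has no positive intensity")

    @property
    def n_channels(self) -> int:
        return int(self.mz.size)

    def channels(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def to_string(self, fmt: str = "%.6g") -> str:
        """Encode as whitespace-separated ``mz:intensity`` tokens."""
        return " ".join(
            f"{fmt % m}:{fmt % i}" for m, i in zip(self.mz, self.intensity)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.mz.shape == other.mz.shape
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )

    def __hash__(self):
        return hash((self.mz.tobytes(), self.intensity.tobytes()))


def parse_spectrum(text: str) -> Spectrum:
    """Parse a ``"mz:intensity mz:intensity ..."`` string into a Spectrum.

    Tokens may appear in any order; duplicate m/z entries are summed
    (robust to centroiding artifacts).
    """
    if not isinstance(text, str) or not text.strip():
        raise SpectrumParseError("empty spectrum string")
    acc: dict[float, float] = {}
    for tok in text.split():
        parts = tok.split(":")
        if len(parts) != 2:
            raise SpectrumParseError(f"malformed spectrum token {tok!r}")
        try:
            m = float(parts[0])
            i = float(parts[1])
        except ValueError as exc:
            raise SpectrumParseError(f"malformed spectrum token {tok!r}") from exc
        acc[m] = acc.get(m, 0.0) + i
    mz = np.array(sorted(acc), dtype=float)
    inten = np.array([acc[m] for m in mz], dtype=float)
    return Spectrum(mz, inten)


def resolve_compound_key(cas: Optional[str], name: Optional[str]) -> Optional[str]:
    """CAS number if present and non-empty, else trimmed lowercase name, else None."""
    if cas is not None and str(cas).strip():
        return str(cas).strip()
    if name is not None and str(name).strip():
        return str(name).strip().lower()
    return None


@dataclass
class Peak:
    """One detected chromatographic peak within a run."""

    peak_id: str
    run_id: str
    rt1: float  # first-dimension retention time (minutes)
    rt2: float  # second-dimension retention time (seconds)
    area: float
    spectrum: Spectrum
    name: Optional[str] = None
    cas: Optional[str] = None
    compound_key: Optional[str] = field(default=None)

    def __post_init__(self):
        if self.rt1 <= 0 or self.rt2 <= 0:
            raise FormatError(
                f"peak {self.peak_id!r}: retention times must be positive "
                f"(rt1={self.rt1}, rt2={self.rt2})"
            )
        if self.area < 0:
            raise FormatError(f"peak {self.peak_id!r}: negative area {self.area}")
        if self.compound_key is None:
            self.compound_key = resolve_compound_key(self.cas, self.name)

    def with_rt(self, rt1: float, rt2: float) -> "Peak":
        return replace(self, rt1=rt1, rt2=rt2)

    def without_key(self) -> "Peak":
        return replace(self, name=None, cas=None, compound_key=None)


class PeakTable:
    """An ordered collection of peaks from a single run.

    Invariants: all peaks share ``run_id``; ``peak_id`` unique within the run.
    """

    def __init__(self, run_id: str, peaks: Iterable[Peak]):
        self.run_id = str(run_id)
        self.peaks: list[Peak] = list(peaks)
        seen: set[str] = set()
        for p in self.peaks:
            if p.run_id != self.run_id:
                raise FormatError(
                    f"peak {p.peak_id!r} has run_id {p.run_id!r}, table is {self.run_id!r}"
                )
            if p.peak_id in seen:
                raise FormatError(f"duplicate peak_id {p.peak_id!r} in run {self.run_id!r}")
            seen.add(p.peak_id)

    @property
    def N(self) -> int:
        return len(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakTable):
            return NotImplemented
        return self.run_id == other.run_id and self.peaks == other.peaks

    def __repr__(self) -> str:
        return f"PeakTable(run_id={self.run_id!r}, N={self.N})"

    def rt1_array(self) -> np.ndarray:
        return np.array([p.rt1 for p in self.peaks], dtype=float)

    def rt2_array(self) -> np.ndarray:
        return np.array([p.rt2 for p in self.peaks], dtype=float)

    def area_array(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks], dtype=float)

    def peak_ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]

    def by_id(self, peak_id: str) -> Peak:
        for p in self.peaks:
            if p.peak_id == peak_id:
                return p
        raise KeyError(peak_id)

    def index_of(self, peak_id: str) -> int:
        for i, p in enumerate(self.peaks):
            if p.peak_id == peak_id:
                return i
        raise KeyError(peak_id)

    def strip_keys(self) -> "PeakTable":
        """Copy with all identification labels removed (key-blind matching)."""
        return PeakTable(self.run_id, [p.without_key() for p in self.peaks])

    def with_run_id(self, run_id: str) -> "PeakTable":
        return PeakTable(run_id, [replace(p, run_id=run_id) for p in self.peaks])
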