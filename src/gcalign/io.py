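"""Reading and writing ChromaTOF-style peak tables.

Peak tables are delimited text (TSV or CSV, autodetected from the file
extension) with one peak per row. The spectrum column encodes the mass
spectrum as whitespace-separated ``mz:intensity`` pairs. Column names vary
between ChromaTOF export layouts, so the mapping from logical fields to
column headers is configurable through a :class:`Dialect`.

Retention-time units are taken as given per file and never rescaled; the
matching method is unit-agnostic (ranks and interpolation), but unit
consistency across runs is the user's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import EmptyInputError, FormatError
from .peaks import Peak, PeakTable, parse_spectrum

logger = logging.getLogger(__name__)

__all__ = ["Dialect", "read_peak_table", "write_aligned_table"]

#: float formatting used on write; round-trip is exact to 6 significant digits
_FLOAT_FMT = "%.6g"


@dataclass
class Dialect:
    """Column mapping for a peak-table file.

    Each logical field lists candidate column headers, tried in order.
    ``peak_id``, ``name`` and ``cas`` are optional in the file; ``rt1``,
    ``rt2``, ``area`` and ``spectrum`` are mandatory.
    """

    peak_id: Sequence[str] = ("Peak ID", "ID")
    name: Sequence[str] = ("Name",)
    cas: Sequence[str] = ("CAS",)
    rt1: Sequence[str] = (
        "1st Dimension Time (min)",
        "1st Dimension Time (s)",
        "RT1",
    )
    rt2: Sequence[str] = ("2nd Dimension Time (s)", "RT2")
    area: Sequence[str] = ("Area",)
    spectrum: Sequence[str] = ("Spectra", "Spectrum")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "Dialect":
        """Build a dialect from a config mapping of field -> header or list."""
        kwargs = {}
        for fld, val in mapping.items():
            if fld not in cls.__dataclass_fields__:
                raise FormatError(f"unknown dialect field {fld!r}")
            kwargs[fld] = (val,) if isinstance(val, str) else tuple(val)
        return cls(**kwargs)

    def find(self, columns: Sequence[str], fld: str) -> Optional[str]:
        for cand in getattr(self, fld):
            if cand in columns:
                return cand
        return None


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_peak_table(
    path: Union[str, Path],
    dialect: Optional[Dialect] = None,
    run_id: Optional[str] = None,
) -> PeakTable:
    """Read a delimited peak table into a :class:`PeakTable`.

    Rows whose retention times or area cannot be parsed are dropped with a
    logged count. Missing mandatory columns or an empty result are errors.
    """
    path = Path(path)
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    cols = list(df.columns)
    resolved: dict[str, Optional[str]] = {
        fld: dialect.find(cols, fld)
        for fld in ("peak_id", "name", "cas", "rt1", "rt2", "area", "spectrum")
    }
    for fld in ("rt1", "rt2", "area", "spectrum"):
        if resolved[fld] is None:
            raise FormatError(
                f"{path.name}: no column for {fld!r} "
                f"(tried {', '.join(getattr(dialect, fld))})"
            )
    rid = run_id if run_id is not None else path.stem
    peaks: list[Peak] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(cols, row))
        try:
            rt1 = float(row[resolved["rt1"]])
            rt2 = float(row[resolved["rt2"]])
            area = float(row[resolved["area"]])
        except (TypeError, ValueError):
            n_rejected += 1
            continue
        spectrum = parse_spectrum(row[resolved["spectrum"]])
        pid = row[resolved["peak_id"]] if resolved["peak_id"] else f"{rid}:{i}"
        name = row[resolved["name"]] if resolved["name"] else None
        cas = row[resolved["cas"]] if resolved["cas"] else None
        try:
            peak = Peak(
                peak_id=str(pid),
                run_id=rid,
                rt1=rt1,
                rt2=rt2,
                area=area,
                spectrum=spectrum,
                name=name or None,
                cas=cas or None,
            )
        except FormatError:
            n_rejected += 1
            continue
        peaks.append(peak)
    if n_rejected:
        logger.warning("%s: rejected %d rows with unparseable RT/area", path, n_rejected)
    if not peaks:
        raise EmptyInputError(f"{path}: no valid peak rows")
    return PeakTable(rid, peaks)


def write_aligned_table(table: PeakTable, path: Union[str, Path]) -> None:
    """Write a peak table as delimited text (format chosen by extension).

    Numeric fields are written at 6 significant digits, so a write/read
    round trip reproduces the table up to that precision.
    """
    if table.N == 0:
        raise EmptyInputError("refusing to write an empty peak table")
    path = Path(path)
    rows = []
    for p in table:
        rows.append(
            {
                "Peak ID": p.peak_id,
                "Name": p.name or "",
                "CAS": p.cas or "",
                "1st Dimension Time (min)": _FLOAT_FMT % p.rt1,
                "2nd Dimension Time (s)": _FLOAT_FMT % p.rt2,
                "Area": _FLOAT_FMT % p.area,
                "Spectra": p.spectrum.to_string(_FLOAT_FMT),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep=_sep_for(path), index=False)
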