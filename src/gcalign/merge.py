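"""Within-run peak merging.

One metabolite species can be reported as several peak entries in a single
run (peak-shape abnormalities, oversensitive detection, short modulation
time). Before alignment, entries sharing the same compound identification
are collapsed to the single entry with maximum peak area; peaks without an
identification pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .peaks import PeakTable

__all__ = ["MergeReport", "merge_peaks"]


@dataclass
class MergeReport:
    """Summary of one merge pass."""

    run_id: str
    n_in: int
    n_out: int
    groups_collapsed: int
    entries_removed: int


def merge_peaks(table: PeakTable) -> tuple[PeakTable, MergeReport]:
    """Collapse same-compound entries to the maximum-area entry.

    Among peaks sharing a non-absent ``compound_key`` exactly the area-argmax
    survives. Area ties break by earlier rt1, then earlier rt2, then input
    order, so output is deterministic. Keyless peaks are never merged (there
    is no identity to group on).

    Returns the merged table and a :class:`MergeReport`.
    """
    best: dict[str, int] = {}  # compound_key -> index of current best peak
    for i, p in enumerate(table):
        if p.compound_key is None:
            continue
        j = best.get(p.compound_key)
        if j is None:
            best[p.compound_key] = i
            continue
        q = table[j]
        # keep p only if strictly better: larger area, then earlier RTs
        if (-p.area, p.rt1, p.rt2, i) < (-q.area, q.rt1, q.rt2, j):
            best[p.compound_key] = i
    keep = set(best.values())
    peaks = [
        p
        for i, p in enumerate(table)
        if p.compound_key is None or i in keep
    ]
    merged = PeakTable(table.run_id, peaks)
    groups = sum(1 for k in best if _group_size(table, k) > 1)
    report = MergeReport(
        run_id=table.run_id,
        n_in=table.N,
        n_out=merged.N,
        groups_collapsed=groups,
        entries_removed=table.N - merged.N,
    )
    return merged, report


def _group_size(table: PeakTable, key: str) -> int:
    return sum(1 for p in table if p.compound_key == key)
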