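"""Evaluation against a name-based gold standard, parameter sweeps, KDE.

The gold standard treats software-assigned compound identities (CAS or
name) as tentatively correct: two merged runs induce one gold-standard pair
per shared compound key. Predicted pairs are scored by positive predictive
value (PPV), sensitivity, and their harmonic mean F1. A grid sweep over the
mixture weight w and the posterior cutoff reports the best F1 per run pair;
best-F1 values are averaged across pairs for a dataset-level summary.

Kernel density estimates of RT distributions serve as a before/after
alignment diagnostic: well-aligned runs pile density at shared RT modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .alignment import MatchPair, pairwise_match
from .errors import DegenerateDataError, ParameterError
from .peaks import PeakTable

__all__ = [
    "EvalReport",
    "gold_standard_pairs",
    "f1_score",
    "parameter_sweep",
    "average_best_f1",
    "kde_profile",
]

PairSet = set[tuple[str, str]]

DEFAULT_W_GRID = (0.1, 0.2, 0.3, 0.5)
DEFAULT_CUTOFF_GRID = (0.6, 0.7, 0.8, 0.9, 0.95)


@dataclass
class EvalReport:
    """PPV/sensitivity/F1 of predicted pairs against the gold standard."""

    n_predicted: int
    n_gs: int
    n_tp: int
    ppv: float
    sensitivity: float
    f1: float
    #: optional sweep grid: {(w, cutoff): f1}
    sweep: Optional[dict[tuple[float, float], float]] = None
    best_cell: Optional[tuple[float, float]] = None
    best_f1: Optional[float] = None


def gold_standard_pairs(ref: PeakTable, target: PeakTable) -> PairSet:
    """Pairs of peaks sharing an identical non-absent compound key.

    Both tables must be merged, so every key appears at most once per run
    and the gold standard is a well-defined pairing. Keyless peaks are
    excluded.
    """
    ref_by_key = {p.compound_key: p.peak_id for p in ref if p.compound_key}
    out: PairSet = set()
    for p in target:
        if p.compound_key and p.compound_key in ref_by_key:
            out.add((ref_by_key[p.compound_key], p.peak_id))
    return out


def _as_pair_set(pairs: Union[Iterable[MatchPair], PairSet]) -> PairSet:
    out: PairSet = set()
    for p in pairs:
        if isinstance(p, MatchPair):
            out.add((p.ref_peak_id, p.target_peak_id))
        else:
            out.add((p[0], p[1]))
    return out


def f1_score(
    predicted: Union[Iterable[MatchPair], PairSet], gs: PairSet
) -> EvalReport:
    """PPV, sensitivity and F1 of predicted pairs against gold-standard pairs.

    F1 = 2 * PPV * sensitivity / (PPV + sensitivity); zero when either
    numerator count is empty.
    """
    pred = _as_pair_set(predicted)
    gs = set(gs)
    tp = len(pred & gs)
    ppv = tp / len(pred) if pred else 0.0
    sens = tp / len(gs) if gs else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if (ppv + sens) > 0 else 0.0
    return EvalReport(
        n_predicted=len(pred),
        n_gs=len(gs),
        n_tp=tp,
        ppv=ppv,
        sensitivity=sens,
        f1=f1,
    )


def parameter_sweep(
    ref: PeakTable,
    target: PeakTable,
    w_grid: Sequence[float] = DEFAULT_W_GRID,
    cutoff_grid: Sequence[float] = DEFAULT_CUTOFF_GRID,
    scale: str = "angle",
    h: float = 40.0,
    **match_kwargs,
) -> EvalReport:
    """F1 over a (w, cutoff) grid against the name-based gold standard.

    Matching is key-blind: compound keys are stripped before alignment so
    the gold standard never leaks into prediction. The returned report holds
    the full grid, the best cell and its F1, plus the counts of that best
    cell.
    """
    if not w_grid or not cutoff_grid:
        raise ParameterError("sweep grids must be non-empty")
    gs = gold_standard_pairs(ref, target)
    ref_blind = ref.strip_keys()
    target_blind = target.strip_keys()
    sweep: dict[tuple[float, float], float] = {}
    best: Optional[EvalReport] = None
    best_cell = None
    for w in w_grid:
        # one match per w at the loosest cutoff; re-threshold for the rest
        cut_min = min(cutoff_grid)
        pairs = pairwise_match(
            ref_blind, target_blind, w=w, scale=scale, h=h, cutoff=cut_min,
            **match_kwargs,
        )
        for cutoff in cutoff_grid:
            kept = [p for p in pairs if p.posterior > cutoff]
            rep = f1_score(kept, gs)
            sweep[(w, cutoff)] = rep.f1
            if best is None or rep.f1 > best.f1:
                best, best_cell = rep, (w, cutoff)
    best.sweep = sweep
    best.best_cell = best_cell
    best.best_f1 = best.f1
    return best


def average_best_f1(reports: Sequence[EvalReport]) -> float:
    """Average of per-pair best F1 values (dataset-level summary)."""
    if not reports:
        raise ParameterError("no reports to average")
    return float(np.mean([r.best_f1 if r.best_f1 is not None else r.f1 for r in reports]))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a Gaussian kernel."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise DegenerateDataError("constant input: bandwidth undefined")
    return 0.9 * spread * values.size ** (-0.2)


def kde_profile(
    values: Sequence[float],
    bandwidth: Union[float, str] = "auto",
    grid_size: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of RT values on a regular grid.

    The grid spans the data plus three bandwidths on either side, so the
    trapezoid mass is 1 up to ~1e-3. Returns (grid, density).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ParameterError("kde_profile needs at least two values")
    bw = silverman_bandwidth(values) if bandwidth == "auto" else float(bandwidth)
    if bw <= 0:
        raise ParameterError("bandwidth must be positive")
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, grid_size)
    z = (grid[:, None] - values[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * bw * np.sqrt(2 * np.pi))
    return grid, dens
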