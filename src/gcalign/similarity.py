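"""Mixture dissimilarity score between peaks: RT rank distance + spectral angle.

The score between peaks A and B is

    S(A, B) = w * D / (1 + D) + (1 - w) * C'

where ``D`` is the Euclidean distance between the peaks' within-run
(rank1, rank2) retention-time rank vectors, ``C`` is the angle in degrees
between their mass spectra, ``w`` in [0, 1] weights the two terms, and the
second term is ``C' = C`` on the default ``"angle"`` scale or ``C' = C/90``
on the ``"normalized"`` scale. Smaller S means more similar — it is a
dissimilarity despite the name. Using elution *ranks* instead of raw RTs
makes the score invariant to monotone RT warps between runs, which is what
lets the same score work for homogeneous and heterogeneous data.

Small weights (w <= 0.5) are preferred so that spectrum similarity
dominates the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.stats import rankdata

from .errors import InvalidSpectrumError, ParameterError
from .peaks import Peak, PeakTable, Spectrum

__all__ = [
    "RankIndex",
    "ScoreMatrix",
    "compute_ranks",
    "rank_distance",
    "cosine_angle",
    "mixture_score",
    "score_matrix",
]

SCALES = ("angle", "normalized")


@dataclass
class RankIndex:
    """Within-run elution ranks per dimension (average ranks for ties)."""

    run_id: str
    rank1: np.ndarray
    rank2: np.ndarray
    normalized: bool = False


def compute_ranks(table: PeakTable, normalize: bool = False) -> RankIndex:
    """Rank peaks by rt1 and rt2 independently; ties get average ranks.

    With ``normalize=True`` ranks are divided by N, which makes rank
    distances comparable between runs of unequal size.
    """
    if table.N < 1:
        raise ParameterError("cannot rank an empty table")
    r1 = rankdata(table.rt1_array(), method="average")
    r2 = rankdata(table.rt2_array(), method="average")
    if normalize:
        r1 = r1 / table.N
        r2 = r2 / table.N
    return RankIndex(table.run_id, r1, r2, normalized=normalize)


def rank_distance(
    peak_a: Union[Peak, int],
    peak_b: Union[Peak, int],
    ranks_a: RankIndex,
    ranks_b: RankIndex,
    table_a: PeakTable = None,
    table_b: PeakTable = None,
) -> float:
    """Euclidean distance between two peaks' 2-D rank vectors.

    Peaks may be given as integer positions within their run, or as
    :class:`Peak` objects together with their tables.
    """
    ia = peak_a if isinstance(peak_a, (int, np.integer)) else table_a.index_of(peak_a.peak_id)
    ib = peak_b if isinstance(peak_b, (int, np.integer)) else table_b.index_of(peak_b.peak_id)
    d1 = ranks_a.rank1[ia] - ranks_b.rank1[ib]
    d2 = ranks_a.rank2[ia] - ranks_b.rank2[ib]
    return float(np.hypot(d1, d2))


def _dense_intensities(
    spectra: list[Spectrum], round_mz: bool = True, sqrt_intensity: bool = False
) -> np.ndarray:
    """Stack spectra on the union of (integer-rounded) m/z channels, zero-filled."""
    keys = [
        np.rint(s.mz).astype(np.int64) if round_mz else s.mz for s in spectra
    ]
    union = np.unique(np.concatenate(keys))
    out = np.zeros((len(spectra), union.size))
    for row, (k, s) in enumerate(zip(keys, spectra)):
        idx = np.searchsorted(union, k)
        # duplicate channels after rounding accumulate
        np.add.at(out[row], idx, s.intensity)
    if sqrt_intensity:
        np.sqrt(out, out=out)
    return out


def _angles_from_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    nx = np.linalg.norm(x, axis=1)
    ny = np.linalg.norm(y, axis=1)
    if np.any(nx == 0) or np.any(ny == 0):
        raise InvalidSpectrumError("zero-norm spectrum in angle computation")
    cos = (x @ y.T) / np.outer(nx, ny)
    np.clip(cos, -1.0, 1.0, out=cos)
    return np.degrees(np.arccos(cos))


def cosine_angle(
    s1: Spectrum, s2: Spectrum, round_mz: bool = True, sqrt_intensity: bool = False
) -> float:
    """Angle in degrees between two spectra on their union m/z support.

    0 for identical (up to positive scaling), 90 for disjoint supports.
    """
    x = _dense_intensities([s1, s2], round_mz=round_mz, sqrt_intensity=sqrt_intensity)
    return float(_angles_from_matrix(x[:1], x[1:])[0, 0])


def mixture_score(
    D: float, C: float, w: float = 0.1, scale: str = "angle"
) -> float:
    """Combine rank distance and spectral angle into the mixture score.

    ``scale="normalized"``: S = w*D/(1+D) + (1-w)*C/90, bounded in [0, 1).
    ``scale="angle"`` (default): S = w*D/(1+D) + (1-w)*C with C in degrees,
    the scale on which the stock candidate threshold h = 40 operates.
    """
    if not 0.0 <= w <= 1.0:
        raise ParameterError(f"weight w must lie in [0, 1], got {w}")
    if scale not in SCALES:
        raise ParameterError(f"scale must be one of {SCALES}, got {scale!r}")
    D = np.asarray(D, dtype=float)
    C = np.asarray(C, dtype=float)
    second = C / 90.0 if scale == "normalized" else C
    out = w * D / (1.0 + D) + (1.0 - w) * second
    return out if out.ndim else float(out)


@dataclass
class ScoreMatrix:
    """All pairwise mixture scores between a reference and a target run.

    ``S[j, l]`` scores reference peak j against target peak l. ``candidates``
    holds, per reference peak, the target indices with score below the
    threshold ``h`` (the peak's plausible match set).
    """

    ref_run_id: str
    target_run_id: str
    S: np.ndarray
    w: float
    scale: str
    h: float
    candidates: list[np.ndarray]

    @property
    def n_ref(self) -> int:
        return self.S.shape[0]

    @property
    def n_target(self) -> int:
        return self.S.shape[1]


def score_matrix(
    ref: PeakTable,
    target: PeakTable,
    w: float = 0.1,
    scale: str = "angle",
    h: float = 40.0,
    normalize_ranks: bool = False,
    round_mz: bool = True,
    sqrt_intensity: bool = False,
) -> ScoreMatrix:
    """Mixture scores for every (reference peak, target peak) pair."""
    if ref.N == 0 or target.N == 0:
        raise ParameterError("score_matrix requires non-empty tables")
    ra = compute_ranks(ref, normalize=normalize_ranks)
    rb = compute_ranks(target, normalize=normalize_ranks)
    d1 = ra.rank1[:, None] - rb.rank1[None, :]
    d2 = ra.rank2[:, None] - rb.rank2[None, :]
    D = np.hypot(d1, d2)
    dense = _dense_intensities(
        [p.spectrum for p in ref] + [p.spectrum for p in target],
        round_mz=round_mz,
        sqrt_intensity=sqrt_intensity,
    )
    C = _angles_from_matrix(dense[: ref.N], dense[ref.N :])
    S = mixture_score(D, C, w=w, scale=scale)
    candidates = [np.flatnonzero(S[j] < h) for j in range(ref.N)]
    return ScoreMatrix(
        ref_run_id=ref.run_id,
        target_run_id=target.run_id,
        S=S,
        w=w,
        scale=scale,
        h=h,
        candidates=candidates,
    )
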