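"""Peak alignment: pairwise matching, landmark chains and RT adjustment.

The alignment pipeline works pairwise-then-chain. For each consecutive pair
of runs, an empirical Bayes model is fitted to the mixture-score matrix and
reference-target pairs whose posterior matching confidence exceeds a cutoff
are retained (one-to-one). Peaks whose pairs link through *every* run form
landmark chains; each chain's mean retention times define a representative
landmark. Per run and per dimension, the landmarks induce a monotone
piecewise-linear map from that run's RTs onto the representative grid,
applied to all peaks simultaneously (lattice-wise, not peak-wise): a peak
at t between bracketing landmark RTs (t_L, t_H) mapping to (r_L, r_H) moves
to r_L + Delta * (r_H - r_L) with Delta = (t - t_L) / (t_H - t_L). The two
dimensions are adjusted sequentially and independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from .ebmodel import (
    EmpiricalBayesMatchModel,
    competition_scores,
    match_states,
)
from .errors import (
    CrossingLandmarksError,
    InsufficientLandmarksError,
    NoLandmarksError,
    NotFittedError,
    ParameterError,
)
from .peaks import PeakTable
from .similarity import score_matrix

__all__ = [
    "MatchPair",
    "LandmarkChain",
    "RtMap",
    "pairwise_match",
    "select_landmarks",
    "build_rt_map",
    "adjust_rt",
    "align_runs",
    "PeakPairMatcher",
    "RetentionTimeAligner",
]


@dataclass(frozen=True)
class MatchPair:
    """A retained reference-target peak pair with its score and confidence."""

    ref_peak_id: str
    target_peak_id: str
    score: float
    posterior: float


@dataclass
class LandmarkChain:
    """One peak per run, linked with high confidence through all runs."""

    members: dict[str, str]  # run_id -> peak_id
    rep_rt1: float
    rep_rt2: float
    mean_posterior: float

    def member_rts(self, runs: dict[str, PeakTable]) -> dict[str, tuple[float, float]]:
        return {
            rid: (runs[rid].by_id(pid).rt1, runs[rid].by_id(pid).rt2)
            for rid, pid in self.members.items()
        }


# ---------------------------------------------------------------------------
# pairwise matching

class PeakPairMatcher(BaseEstimator):
    """Pairwise peak matching between two runs (sklearn-style estimator).

    ``fit(ref, target)`` runs the full pipeline — score matrix, competition
    scores, EM fit, posteriors — and stores the retained one-to-one pairs in
    ``pairs_`` plus the fitted ``model_``.

    Parameters mirror the method's operating point: mixture weight ``w``,
    score ``scale``, candidate threshold ``h`` (on the active score scale)
    and posterior ``cutoff``.
    """

    def __init__(
        self,
        w: float = 0.1,
        scale: str = "angle",
        h: float = 40.0,
        cutoff: float = 0.9,
        normalize_ranks: bool = False,
        f_F_components: int = 1,
        tol: float = 1e-8,
        max_iter: int = 500,
        seed: Optional[int] = None,
    ):
        self.w = w
        self.scale = scale
        self.h = h
        self.cutoff = cutoff
        self.normalize_ranks = normalize_ranks
        self.f_F_components = f_F_components
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, ref: PeakTable, target: PeakTable):
        if not 0.0 <= self.cutoff <= 1.0:
            raise ParameterError(f"cutoff must lie in [0, 1], got {self.cutoff}")
        sm = score_matrix(
            ref,
            target,
            w=self.w,
            scale=self.scale,
            h=self.h,
            normalize_ranks=self.normalize_ranks,
        )
        self_sm = score_matrix(
            ref, ref, w=self.w, scale=self.scale, h=self.h,
            normalize_ranks=self.normalize_ranks,
        )
        comp = competition_scores(ref, self_sm)
        states = match_states(sm)
        model = EmpiricalBayesMatchModel(
            tol=self.tol,
            max_iter=self.max_iter,
            f_F_components=self.f_F_components,
            seed=self.seed,
        ).fit(states, comp)
        post = model.predict_proba(states, comp)

        # collect best-candidate pairs above the cutoff
        raw: list[tuple[int, int, float, float]] = []
        for j in np.flatnonzero(states.z):
            if post[j] > self.cutoff:
                l = states.best_target_index(int(j))
                raw.append((int(j), l, float(sm.S[j, l]), float(post[j])))
        pairs = _resolve_one_to_one(raw, ref, target)

        self.model_ = model
        self.states_ = states
        self.score_matrix_ = sm
        self.competition_ = comp
        self.pairs_ = pairs
        return self


def _resolve_one_to_one(
    raw: Sequence[tuple[int, int, float, float]], ref: PeakTable, target: PeakTable
) -> list[MatchPair]:
    """Keep at most one pair per target peak: highest posterior, then
    smaller score, then smaller reference id."""
    ref_ids = ref.peak_ids()
    by_target: dict[int, tuple] = {}
    for j, l, s, p in raw:
        key = (-p, s, ref_ids[j])
        if l not in by_target or key < by_target[l][0]:
            by_target[l] = (key, j, s, p)
    tgt_ids = target.peak_ids()
    out = [
        MatchPair(
            ref_peak_id=ref_ids[j],
            target_peak_id=tgt_ids[l],
            score=s,
            posterior=p,
        )
        for l, (_, j, s, p) in sorted(by_target.items())
    ]
    return out


def pairwise_match(
    ref: PeakTable,
    target: PeakTable,
    w: float = 0.1,
    scale: str = "angle",
    h: float = 40.0,
    cutoff: float = 0.9,
    **kwargs,
) -> list[MatchPair]:
    """Match two merged runs; retain confident one-to-one pairs."""
    return PeakPairMatcher(w=w, scale=scale, h=h, cutoff=cutoff, **kwargs).fit(
        ref, target
    ).pairs_


# ---------------------------------------------------------------------------
# landmark chains

def select_landmarks(
    runs: Sequence[PeakTable],
    pair_lists: Sequence[Sequence[MatchPair]],
    pairing: str = "consecutive",
) -> list[LandmarkChain]:
    """Chain confidently matched peaks through all runs.

    ``pairing="consecutive"`` expects one pair list per consecutive run pair
    (run i vs run i+1, in the given order); a chain is a path linking one
    peak per run. ``pairing="all"`` expects pair lists for every ordered
    run pair i < j and requires chains to be mutually consistent cliques.
    Chains are ranked by mean link posterior; because matching is
    one-to-one, chains never share peaks.
    """
    if len(runs) < 2:
        raise ParameterError("landmark selection needs at least two runs")
    if pairing == "consecutive":
        chains = _chains_consecutive(runs, pair_lists)
    elif pairing == "all":
        chains = _chains_all_pairs(runs, pair_lists)
    else:
        raise ParameterError(f"unknown pairing {pairing!r}")
    chains.sort(key=lambda c: -c.mean_posterior)
    return chains


def _chains_consecutive(runs, pair_lists) -> list[LandmarkChain]:
    if len(pair_lists) != len(runs) - 1:
        raise ParameterError(
            f"expected {len(runs) - 1} pair lists for consecutive pairing, "
            f"got {len(pair_lists)}"
        )
    maps = []
    for pairs in pair_lists:
        maps.append({p.ref_peak_id: p for p in pairs})
    chains = []
    for start in runs[0]:
        member_ids = [start.peak_id]
        posts = []
        pid = start.peak_id
        ok = True
        for m in maps:
            pair = m.get(pid)
            if pair is None:
                ok = False
                break
            posts.append(pair.posterior)
            pid = pair.target_peak_id
            member_ids.append(pid)
        if not ok:
            continue
        chains.append(_make_chain(runs, member_ids, posts))
    return chains


def _chains_all_pairs(runs, pair_lists) -> list[LandmarkChain]:
    n = len(runs)
    expected = n * (n - 1) // 2
    if len(pair_lists) != expected:
        raise ParameterError(
            f"expected {expected} pair lists for all-pairs pairing, got {len(pair_lists)}"
        )
    # index pair lists by (i, j), i < j, in row-major order
    edges: dict[tuple[int, int], dict[str, MatchPair]] = {}
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            edges[(i, j)] = {p.ref_peak_id: p for p in pair_lists[k]}
            k += 1
    chains = []
    for start in runs[0]:
        member_ids = [start.peak_id]
        posts = []
        ok = True
        for j in range(1, n):
            pair = edges[(0, j)].get(start.peak_id)
            if pair is None:
                ok = False
                break
            member_ids.append(pair.target_peak_id)
            posts.append(pair.posterior)
        if not ok:
            continue
        # clique consistency: every intermediate pair must agree
        for i in range(1, n):
            for j in range(i + 1, n):
                pair = edges[(i, j)].get(member_ids[i])
                if pair is None or pair.target_peak_id != member_ids[j]:
                    ok = False
                    break
                posts.append(pair.posterior)
            if not ok:
                break
        if ok:
            chains.append(_make_chain(runs, member_ids, posts))
    return chains


def _make_chain(runs, member_ids, posts) -> LandmarkChain:
    members = {run.run_id: pid for run, pid in zip(runs, member_ids)}
    rts = [runs[i].by_id(member_ids[i]) for i in range(len(runs))]
    return LandmarkChain(
        members=members,
        rep_rt1=float(np.mean([p.rt1 for p in rts])),
        rep_rt2=float(np.mean([p.rt2 for p in rts])),
        mean_posterior=float(np.mean(posts)) if posts else 0.0,
    )


# ---------------------------------------------------------------------------
# RT maps

@dataclass
class RtMap:
    """Monotone piecewise-linear RT correction map for one dimension.

    ``knots_t`` are a target run's landmark RTs (strictly increasing),
    ``knots_r`` the corresponding representative RTs (strictly increasing).
    Between knots the map interpolates linearly; outside the knot span it
    extrapolates linearly from the two outermost knots; at a knot it returns
    the representative RT exactly.
    """

    dimension: int
    knots_t: np.ndarray
    knots_r: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.knots_t, dtype=float)
        r = np.asarray(self.knots_r, dtype=float)
        self.knots_t, self.knots_r = t, r
        if t.size < 2:
            raise InsufficientLandmarksError(
                f"dimension {self.dimension}: need >= 2 distinct landmark knots, got {t.size}"
            )
        if not np.all(np.diff(t) > 0):
            raise ParameterError("knot target RTs must be strictly increasing")
        if not np.all(np.diff(r) > 0):
            bad = int(np.flatnonzero(np.diff(r) <= 0)[0])
            raise CrossingLandmarksError(
                f"dimension {self.dimension}: representative RTs not increasing "
                f"between knots {t[bad]:.6g}->{r[bad]:.6g} and {t[bad + 1]:.6g}->{r[bad + 1]:.6g}",
                knots=((t[bad], r[bad]), (t[bad + 1], r[bad + 1])),
            )

    def __call__(self, t_m):
        return adjust_rt(self, t_m)


def build_rt_map(
    chains: Sequence[LandmarkChain],
    runs: Union[Sequence[PeakTable], dict[str, PeakTable]],
    target_run: str,
    dimension: int,
    resolution: Union[float, str, None] = "auto",
) -> RtMap:
    """Build the per-dimension landmark map for one run.

    Knots pair the target run's landmark RTs with the representative RTs.
    Landmarks sharing an identical target RT collapse to a single knot whose
    representative value is the mean of their partners. Landmarks tied only
    up to measurement precision — adjacent knots whose representative RTs
    invert by a small amount — likewise collapse to their weighted average
    (pool-adjacent-violators); ``resolution`` bounds how far the repair may
    move a representative RT (``"auto"`` = 2% of the representative span;
    0 or None = strict). A larger inversion signals genuinely bad matching
    and raises :class:`CrossingLandmarksError`.
    """
    if dimension not in (1, 2):
        raise ParameterError("dimension must be 1 or 2")
    if len(chains) < 2:
        raise InsufficientLandmarksError("need at least two landmark chains")
    run_map = (
        runs if isinstance(runs, dict) else {r.run_id: r for r in runs}
    )
    if target_run not in run_map:
        raise ParameterError(f"unknown run {target_run!r}")
    table = run_map[target_run]
    pts: dict[float, list[float]] = {}
    for c in chains:
        pid = c.members[target_run]
        peak = table.by_id(pid)
        t = peak.rt1 if dimension == 1 else peak.rt2
        r = c.rep_rt1 if dimension == 1 else c.rep_rt2
        pts.setdefault(t, []).append(r)
    t_knots = np.array(sorted(pts))
    r_knots = np.array([float(np.mean(pts[t])) for t in t_knots])
    wts = np.array([float(len(pts[t])) for t in t_knots])
    if resolution == "auto":
        res = 0.02 * (r_knots.max() - r_knots.min()) if t_knots.size > 1 else 0.0
    else:
        res = float(resolution) if resolution else 0.0
    t_knots, r_knots = _collapse_tied_knots(t_knots, r_knots, wts, res, dimension)
    return RtMap(dimension=dimension, knots_t=t_knots, knots_r=r_knots)


def _collapse_tied_knots(t, r, w, res, dimension):
    """Restore monotonicity by pool-adjacent-violators: adjacent knots whose
    representative RTs invert merge into their weighted average (both
    coordinates), iterated to a fixed point. Landmarks tied within
    measurement precision are thereby collapsed; if the repair has to move
    any representative RT by more than ``res``, the inversion is too large
    to be a tie — it signals bad matching — and the offending knots raise
    :class:`CrossingLandmarksError` instead of being silently repaired."""
    t, r, w = list(t), list(r), list(w)
    i = 0
    while i < len(t) - 1:
        if r[i + 1] - r[i] <= 0:
            dr = r[i] - r[i + 1]
            if dr / 2.0 > res:
                raise CrossingLandmarksError(
                    f"dimension {dimension}: representative RTs not increasing "
                    f"between knots {t[i]:.6g}->{r[i]:.6g} and "
                    f"{t[i + 1]:.6g}->{r[i + 1]:.6g}",
                    knots=((t[i], r[i]), (t[i + 1], r[i + 1])),
                )
            tw = w[i] + w[i + 1]
            t[i] = (w[i] * t[i] + w[i + 1] * t[i + 1]) / tw
            r[i] = (w[i] * r[i] + w[i + 1] * r[i + 1]) / tw
            w[i] = tw
            del t[i + 1], r[i + 1], w[i + 1]
            i = max(i - 1, 0)  # re-check against the previous knot
        else:
            i += 1
    return np.asarray(t), np.asarray(r)


def adjust_rt(rt_map: RtMap, t_m):
    """Apply a landmark map to one RT or an array of RTs.

    Piecewise-linear between knots, linear extrapolation outside, and exact
    at the knots themselves.
    """
    t = rt_map.knots_t
    r = rt_map.knots_r
    x = np.asarray(t_m, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    hi = np.clip(np.searchsorted(t, x, side="left"), 1, t.size - 1)
    lo = hi - 1
    delta = (x - t[lo]) / (t[hi] - t[lo])
    out = r[lo] + delta * (r[hi] - r[lo])
    # knot exactness
    pos = np.searchsorted(t, x)
    on_knot = (pos < t.size) & (t[np.minimum(pos, t.size - 1)] == x)
    out[on_knot] = r[pos[on_knot]]
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# end-to-end alignment

class RetentionTimeAligner(BaseEstimator):
    """Multi-run landmark alignment (sklearn-style fit/transform).

    ``fit(runs)`` matches consecutive run pairs, selects landmark chains and
    builds per-run, per-dimension RT maps; ``transform(runs)`` returns the
    runs with adjusted retention times (non-RT fields untouched).
    """

    def __init__(
        self,
        w: float = 0.1,
        scale: str = "angle",
        h: float = 40.0,
        cutoff: float = 0.9,
        pairing: str = "consecutive",
        normalize_ranks: bool = False,
        f_F_components: int = 1,
        knot_resolution: Union[float, str, None] = "auto",
        seed: Optional[int] = None,
    ):
        self.w = w
        self.scale = scale
        self.h = h
        self.cutoff = cutoff
        self.pairing = pairing
        self.normalize_ranks = normalize_ranks
        self.f_F_components = f_F_components
        self.knot_resolution = knot_resolution
        self.seed = seed

    def _matcher(self) -> PeakPairMatcher:
        return PeakPairMatcher(
            w=self.w,
            scale=self.scale,
            h=self.h,
            cutoff=self.cutoff,
            normalize_ranks=self.normalize_ranks,
            f_F_components=self.f_F_components,
            seed=self.seed,
        )

    def fit(self, runs: Sequence[PeakTable]):
        if len(runs) < 2:
            raise ParameterError("alignment needs at least two runs")
        pair_lists: list[list[MatchPair]] = []
        matchers: list[PeakPairMatcher] = []
        if self.pairing == "consecutive":
            run_pairs = [(i, i + 1) for i in range(len(runs) - 1)]
        elif self.pairing == "all":
            run_pairs = [
                (i, j) for i in range(len(runs)) for j in range(i + 1, len(runs))
            ]
        else:
            raise ParameterError(f"unknown pairing {self.pairing!r}")
        for i, j in run_pairs:
            m = self._matcher().fit(runs[i], runs[j])
            matchers.append(m)
            pair_lists.append(m.pairs_)
        chains = select_landmarks(runs, pair_lists, pairing=self.pairing)
        if not chains:
            raise NoLandmarksError(
                "no peak chains span all runs; cannot build landmark grid"
            )
        maps: dict[str, dict[int, RtMap]] = {}
        for run in runs:
            maps[run.run_id] = {
                d: build_rt_map(
                    chains, runs, run.run_id, d, resolution=self.knot_resolution
                )
                for d in (1, 2)
            }
        self.pair_lists_ = pair_lists
        self.matchers_ = matchers
        self.chains_ = chains
        self.rt_maps_ = maps
        return self

    def transform(self, runs: Sequence[PeakTable]) -> list[PeakTable]:
        if not hasattr(self, "rt_maps_"):
            raise NotFittedError("call fit before transform")
        out = []
        for run in runs:
            if run.run_id not in self.rt_maps_:
                raise ParameterError(f"run {run.run_id!r} was not seen during fit")
            m1 = self.rt_maps_[run.run_id][1]
            m2 = self.rt_maps_[run.run_id][2]
            new_rt1 = adjust_rt(m1, run.rt1_array())
            new_rt2 = adjust_rt(m2, run.rt2_array())
            out.append(
                PeakTable(
                    run.run_id,
                    [
                        p.with_rt(float(t1), float(t2))
                        for p, t1, t2 in zip(run, new_rt1, new_rt2)
                    ],
                )
            )
        return out

    def fit_transform(self, runs: Sequence[PeakTable]) -> list[PeakTable]:
        return self.fit(runs).transform(runs)


def align_runs(
    runs: Sequence[PeakTable],
    w: float = 0.1,
    scale: str = "angle",
    h: float = 40.0,
    cutoff: float = 0.9,
    pairing: str = "consecutive",
    **kwargs,
) -> tuple[list[PeakTable], list[LandmarkChain]]:
    """Align multiple merged runs; returns adjusted runs and landmark chains."""
    aligner = RetentionTimeAligner(
        w=w, scale=scale, h=h, cutoff=cutoff, pairing=pairing, **kwargs
    )
    adjusted = aligner.fit_transform(runs)
    return adjusted, aligner.chains_
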