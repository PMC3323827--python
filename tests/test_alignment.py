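"""Pairwise matching, landmark chains and piecewise-linear RT adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcalign.alignment import (
    LandmarkChain,
    MatchPair,
    RetentionTimeAligner,
    RtMap,
    adjust_rt,
    align_runs,
    build_rt_map,
    pairwise_match,
    select_landmarks,
)
from gcalign.errors import (
    CrossingLandmarksError,
    InsufficientLandmarksError,
    NoLandmarksError,
    ParameterError,
)
from gcalign.merge import merge_peaks
from gcalign.peaks import PeakTable
from gcalign.synthetic import heterogeneous_config, homogeneous_config, simulate_dataset

from conftest import make_peak


# ---------------------------------------------------------------------------
# RT maps

class TestAdjustRt:
    def test_at_lower_knot(self):
        m = RtMap(1, np.array([1.0, 3.0]), np.array([10.0, 14.0]))
        assert adjust_rt(m, 1.0) == 10.0

    def test_midpoint(self):
        m = RtMap(1, np.array([1.0, 3.0]), np.array([10.0, 14.0]))
        assert adjust_rt(m, 2.0) == pytest.approx(12.0)

    def test_extrapolation_above(self):
        # Delta = 1.5 beyond the span
        m = RtMap(1, np.array([1.0, 3.0]), np.array([10.0, 14.0]))
        assert adjust_rt(m, 4.0) == pytest.approx(16.0)

    def test_extrapolation_below(self):
        m = RtMap(1, np.array([1.0, 3.0]), np.array([10.0, 14.0]))
        assert adjust_rt(m, 0.0) == pytest.approx(8.0)

    def test_vectorized(self):
        m = RtMap(1, np.array([1.0, 3.0]), np.array([10.0, 14.0]))
        np.testing.assert_allclose(
            adjust_rt(m, np.array([1.0, 2.0, 3.0])), [10.0, 12.0, 14.0]
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_random_maps_knot_exact_monotone_identity(self, seed):
        """Property suite over random RtMaps: exactness at knots, strict
        monotonicity over the real line, identity when r equals t."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        t = np.sort(rng.uniform(0, 100, k))
        while np.any(np.diff(t) <= 1e-9):
            t = np.sort(rng.uniform(0, 100, k))
        r = np.cumsum(rng.uniform(0.1, 5.0, k)) + rng.uniform(-10, 10)
        m = RtMap(1, t, r)
        # knot exactness (bitwise)
        out = adjust_rt(m, t)
        assert (out == r).all()
        # strict monotonicity on random probe points
        x = np.sort(rng.uniform(t[0] - 20, t[-1] + 20, 50))
        x = np.unique(x)
        y = adjust_rt(m, x)
        assert (np.diff(y) > 0).all()
        # identity map when r == t
        ident = RtMap(1, t, t.copy())
        xs = rng.uniform(t[0], t[-1], 20)
        np.testing.assert_allclose(adjust_rt(ident, xs), xs, atol=1e-9)


class TestBuildRtMap:
    def _chains(self, spec):
        """spec: list of (t, r) for a single run 'X'."""
        chains, table_peaks = [], []
        for i, (t, r) in enumerate(spec):
            pid = f"x{i}"
            table_peaks.append(make_peak(pid, rid="X", rt1=t, rt2=1.0 + 0.1 * i))
            chains.append(LandmarkChain(
                members={"X": pid}, rep_rt1=r, rep_rt2=1.0 + 0.1 * i,
                mean_posterior=0.95,
            ))
        return chains, PeakTable("X", table_peaks)

    def test_two_knot_map(self):
        chains, table = self._chains([(1.0, 2.0), (3.0, 5.0)])
        m = build_rt_map(chains, [table], "X", 1)
        np.testing.assert_allclose(m.knots_t, [1.0, 3.0])
        np.testing.assert_allclose(m.knots_r, [2.0, 5.0])

    def test_identity_when_rep_equals_target(self):
        chains, table = self._chains([(1.0, 1.0), (2.0, 2.0), (4.0, 4.0)])
        m = build_rt_map(chains, [table], "X", 1)
        for x in (1.0, 1.7, 3.2, 4.0):
            assert adjust_rt(m, x) == pytest.approx(x)

    def test_duplicate_target_rt_collapses_to_mean(self):
        chains, table = self._chains([(1.0, 2.0), (3.0, 5.0), (3.0, 7.0)])
        m = build_rt_map(chains, [table], "X", 1)
        np.testing.assert_allclose(m.knots_t, [1.0, 3.0])
        np.testing.assert_allclose(m.knots_r, [2.0, 6.0])  # mean of 5 and 7

    def test_large_crossing_is_hard_error(self):
        chains, table = self._chains([(1.0, 10.0), (5.0, 3.0)])
        with pytest.raises(CrossingLandmarksError):
            build_rt_map(chains, [table], "X", 1)

    def test_small_crossing_collapses_within_resolution(self):
        # a near-tie (dt, |dr| tiny vs span) merges instead of erroring
        chains, table = self._chains([(1.0, 1.0), (5.0, 5.001), (5.01, 5.0), (9.0, 9.0)])
        m = build_rt_map(chains, [table], "X", 1)
        assert m.knots_t.size == 3
        assert (np.diff(m.knots_r) > 0).all()

    def test_strict_mode_raises_on_small_crossing(self):
        chains, table = self._chains([(1.0, 1.0), (5.0, 5.001), (5.01, 5.0), (9.0, 9.0)])
        with pytest.raises(CrossingLandmarksError):
            build_rt_map(chains, [table], "X", 1, resolution=0)

    def test_single_chain_insufficient(self):
        chains, table = self._chains([(1.0, 2.0)])
        with pytest.raises(InsufficientLandmarksError):
            build_rt_map(chains, [table], "X", 1)


# ---------------------------------------------------------------------------
# landmark chains

def _mp(a, b, post=0.95):
    return MatchPair(ref_peak_id=a, target_peak_id=b, score=1.0, posterior=post)


class TestSelectLandmarks:
    def _runs(self, n_runs, n_peaks):
        runs = []
        for r in range(n_runs):
            rid = f"C{r + 1}"
            runs.append(PeakTable(rid, [
                make_peak(f"{rid}p{i}", rid=rid, rt1=10.0 + i, rt2=2.0 + 0.1 * i)
                for i in range(n_peaks)
            ]))
        return runs

    def test_three_runs_six_full_chains(self):
        """Six peaks linked through all three outputs yield six chains."""
        runs = self._runs(3, 8)
        pairs_12 = [_mp(f"C1p{i}", f"C2p{i}") for i in range(6)]
        pairs_23 = [_mp(f"C2p{i}", f"C3p{i}") for i in range(6)]
        # extra partial links that must not form chains
        pairs_12.append(_mp("C1p6", "C2p7"))
        chains = select_landmarks(runs, [pairs_12, pairs_23])
        assert len(chains) == 6
        for c in chains:
            assert set(c.members) == {"C1", "C2", "C3"}

    def test_two_runs_chains_equal_pairs(self):
        runs = self._runs(2, 4)
        pairs = [_mp("C1p0", "C2p1"), _mp("C1p2", "C2p3")]
        chains = select_landmarks(runs, [pairs])
        assert len(chains) == 2
        members = {frozenset(c.members.values()) for c in chains}
        assert members == {frozenset({"C1p0", "C2p1"}), frozenset({"C1p2", "C2p3"})}

    def test_broken_link_excludes_peak(self):
        runs = self._runs(3, 3)
        pairs_12 = [_mp("C1p0", "C2p0"), _mp("C1p1", "C2p1")]
        pairs_23 = [_mp("C2p0", "C3p0")]  # p1 matches C1<->C2 but not C2<->C3
        chains = select_landmarks(runs, [pairs_12, pairs_23])
        assert len(chains) == 1
        assert chains[0].members["C1"] == "C1p0"

    def test_rep_rts_are_member_means(self):
        runs = self._runs(2, 2)
        chains = select_landmarks(runs, [[_mp("C1p0", "C2p1")]])
        c = chains[0]
        p1 = runs[0].by_id("C1p0")
        p2 = runs[1].by_id("C2p1")
        assert c.rep_rt1 == pytest.approx((p1.rt1 + p2.rt1) / 2)
        assert c.rep_rt2 == pytest.approx((p1.rt2 + p2.rt2) / 2)

    def test_fewer_than_two_runs_rejected(self):
        with pytest.raises(ParameterError):
            select_landmarks(self._runs(1, 3), [])

    def test_no_peak_in_two_chains(self):
        runs = self._runs(3, 6)
        pairs_12 = [_mp(f"C1p{i}", f"C2p{i}") for i in range(6)]
        pairs_23 = [_mp(f"C2p{i}", f"C3p{(i + 1) % 6}") for i in range(6)]
        chains = select_landmarks(runs, [pairs_12, pairs_23])
        seen = set()
        for c in chains:
            for rid, pid in c.members.items():
                assert (rid, pid) not in seen
                seen.add((rid, pid))


# ---------------------------------------------------------------------------
# pairwise matching and end-to-end alignment on synthetic data

class TestPairwiseMatch:
    def test_self_match_recovers_every_peak(self):
        cfg = homogeneous_config(n_metabolites=40, n_runs=1, dropout_rate=0.0,
                                 split_rate=0.0, label_error_rate=0.0, seed=9)
        runs, _, _ = simulate_dataset(cfg)
        ref = runs[0]
        target = ref.with_run_id("copy")
        pairs = pairwise_match(ref, target, cutoff=0.9)
        assert len(pairs) == ref.N
        for p in pairs:
            assert ref.index_of(p.ref_peak_id) == target.index_of(p.target_peak_id)
            assert p.posterior > 0.9

    def test_cutoff_one_empties_pairs(self):
        cfg = homogeneous_config(n_metabolites=30, n_runs=1, dropout_rate=0.0,
                                 split_rate=0.0, label_error_rate=0.0, seed=9)
        runs, _, _ = simulate_dataset(cfg)
        ref = runs[0]
        pairs = pairwise_match(ref, ref.with_run_id("copy"), cutoff=1.0)
        assert pairs == []

    def test_invalid_cutoff_rejected(self, three_peak_table):
        with pytest.raises(ParameterError):
            pairwise_match(three_peak_table, three_peak_table, cutoff=1.5)

    def test_shared_and_specific_peaks(self):
        """30 shared + 10 run-specific peaks, mild warp: the true pairs are
        recovered and no run-specific peak is ever matched."""
        cfg = heterogeneous_config(
            n_metabolites=40, n_runs=2, dropout_rate=0.0, split_rate=0.0,
            label_error_rate=0.0, seed=17,
        )
        runs, truth, master = simulate_dataset(cfg)
        ref, target = runs
        # drop 10 metabolites from each run (disjoint sets) -> 20 shared
        ref_drop = {f"M{i:04d}" for i in range(10)}
        tgt_drop = {f"M{i:04d}" for i in range(10, 20)}
        tmap = dict(zip(truth.peak_id, truth.metabolite_id))
        ref2 = PeakTable(ref.run_id, [p for p in ref if tmap[p.peak_id] not in ref_drop])
        tgt2 = PeakTable(target.run_id, [p for p in target if tmap[p.peak_id] not in tgt_drop])
        pairs = pairwise_match(ref2.strip_keys(), tgt2.strip_keys(), cutoff=0.9)
        true_pairs = sum(
            1 for p in pairs if tmap[p.ref_peak_id] == tmap[p.target_peak_id]
        )
        shared = 20
        assert true_pairs >= shared * 0.9
        for p in pairs:  # no pair may involve a run-specific metabolite
            assert tmap[p.ref_peak_id] not in tgt_drop
            assert tmap[p.target_peak_id] not in ref_drop

    def test_one_to_one(self):
        cfg = homogeneous_config(n_metabolites=50, n_runs=2, dropout_rate=0.1,
                                 split_rate=0.0, label_error_rate=0.0, seed=23)
        runs, _, _ = simulate_dataset(cfg)
        pairs = pairwise_match(runs[0], runs[1], cutoff=0.5)
        refs = [p.ref_peak_id for p in pairs]
        tgts = [p.target_peak_id for p in pairs]
        assert len(refs) == len(set(refs))
        assert len(tgts) == len(set(tgts))


class TestAlignRuns:
    def test_identical_runs_alignment_is_identity(self):
        cfg = homogeneous_config(n_metabolites=30, n_runs=1, dropout_rate=0.0,
                                 split_rate=0.0, label_error_rate=0.0, seed=31)
        runs, _, _ = simulate_dataset(cfg)
        copies = [runs[0].with_run_id(f"c{i}") for i in range(3)]
        adjusted, chains = align_runs(copies)
        assert len(chains) > 0
        for orig, adj in zip(copies, adjusted):
            np.testing.assert_allclose(adj.rt1_array(), orig.rt1_array(), atol=1e-9)
            np.testing.assert_allclose(adj.rt2_array(), orig.rt2_array(), atol=1e-9)

    def test_affine_warps_inverted(self):
        """Post-alignment RT spread across runs shrinks by >= 90%."""
        cfg = heterogeneous_config(
            n_metabolites=60, n_runs=3, dropout_rate=0.05, split_rate=0.0,
            label_error_rate=0.0, seed=37,
        )
        runs, truth, _ = simulate_dataset(cfg)
        merged = [merge_peaks(r)[0] for r in runs]
        adjusted, chains = align_runs([m.strip_keys() for m in merged])
        t = truth[~truth.is_split]

        def mean_sd(tables):
            lut = {(r.run_id, p.peak_id): (p.rt1, p.rt2) for r in tables for p in r}
            sds = []
            for _, g in t.groupby("metabolite_id"):
                pts = [lut[(r, p)] for r, p in zip(g.run_id, g.peak_id) if (r, p) in lut]
                if len(pts) == len(runs):
                    a = np.array(pts)
                    sds.append([a[:, 0].std(), a[:, 1].std()])
            return np.array(sds).mean(axis=0)

        before = mean_sd(merged)
        after = mean_sd(adjusted)
        assert (after <= 0.1 * before).all()

    def test_landmark_members_land_on_representative_rts(self):
        cfg = homogeneous_config(n_metabolites=25, n_runs=3, dropout_rate=0.0,
                                 split_rate=0.0, label_error_rate=0.0, seed=41,
                                 jitter_sd1=0.0, jitter_sd2=0.0)
        runs, _, _ = simulate_dataset(cfg)
        aligner = RetentionTimeAligner().fit(runs)
        adjusted = aligner.transform(runs)
        adj = {r.run_id: r for r in adjusted}
        for c in aligner.chains_:
            for rid, pid in c.members.items():
                p = adj[rid].by_id(pid)
                assert p.rt1 == pytest.approx(c.rep_rt1, abs=1e-9)
                assert p.rt2 == pytest.approx(c.rep_rt2, abs=1e-9)

    def test_order_preserved_within_run(self):
        cfg = heterogeneous_config(n_metabolites=40, n_runs=3, dropout_rate=0.0,
                                   split_rate=0.0, label_error_rate=0.0, seed=43)
        runs, _, _ = simulate_dataset(cfg)
        adjusted, _ = align_runs(runs)
        for orig, adj in zip(runs, adjusted):
            order_before = np.argsort(orig.rt1_array())
            order_after = np.argsort(adj.rt1_array())
            np.testing.assert_array_equal(order_before, order_after)

    def test_non_rt_fields_unchanged(self):
        cfg = homogeneous_config(n_metabolites=20, n_runs=2, dropout_rate=0.0,
                                 split_rate=0.0, label_error_rate=0.0, seed=47)
        runs, _, _ = simulate_dataset(cfg)
        adjusted, _ = align_runs(runs)
        for orig, adj in zip(runs, adjusted):
            for a, b in zip(orig, adj):
                assert a.peak_id == b.peak_id
                assert a.area == b.area
                assert a.spectrum == b.spectrum
                assert a.compound_key == b.compound_key

    def test_single_run_rejected(self, three_peak_table):
        with pytest.raises(ParameterError):
            align_runs([three_peak_table])
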