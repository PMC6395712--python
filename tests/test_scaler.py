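"""Partitioning, bucket combining, selection, and the full scaled run."""

import itertools

import numpy as np
import pytest

from tightscale import (
    Bucket,
    CoreParams,
    DecisionRule,
    ExpressionMatrix,
    TightnessRule,
    advance,
    combine,
    fill_bucket,
    partition,
    plan,
    run,
    select_tightest,
    sigma,
)


class TestPartition:
    def test_sizes_disjoint_and_covering(self, rng):
        active = np.arange(10)
        reps = partition(active, L=2, R=1, seed_or_rng=rng)
        (a, b), = reps
        assert len(a) == len(b) == 5
        assert set(a.tolist()) | set(b.tolist()) == set(range(10))
        assert not set(a.tolist()) & set(b.tolist())

    def test_every_repetition_covers_active_rows(self, rng):
        active = np.array([3, 7, 11, 12, 20, 21, 33])
        for parts in partition(active, L=3, R=5, seed_or_rng=rng):
            got = np.sort(np.concatenate(parts))
            np.testing.assert_array_equal(got, np.sort(active))
            assert max(len(p) for p in parts) - min(len(p) for p in parts) <= 1

    def test_cooccurrence_matches_uniform_partition_probability(self):
        # 6 rows into 3 parts of 2: enumerate all 6!/(2!^3 3!) = 15 pairings;
        # a fixed pair shares a part in 3 of them -> probability 1/5
        def together(perm):
            parts = [set(perm[0:2]), set(perm[2:4]), set(perm[4:6])]
            return any({0, 1} <= p for p in parts)

        exact = np.mean([together(p) for p in itertools.permutations(range(6))])
        assert exact == pytest.approx(0.2)
        reps = partition(np.arange(6), L=3, R=500, seed_or_rng=0)
        freq = np.mean(
            [any({0, 1} <= set(p.tolist()) for p in parts) for parts in reps]
        )
        assert freq == pytest.approx(exact, abs=0.05)

    def test_more_parts_than_rows_rejected(self):
        with pytest.raises(ValueError):
            partition(np.arange(3), L=4, R=1, seed_or_rng=0)


@pytest.fixture
def far_blob_matrix(blob_builder):
    rng = np.random.default_rng(7)
    centers = np.array([[0, 0], [50, 0], [0, 50], [50, 50]], dtype=float)
    m, lab = blob_builder(rng, centers, [30, 30, 30, 30], 0.5)
    return m, lab


class TestFillBucket:
    def test_new_entries_appended_after_existing(self, far_blob_matrix):
        m, _ = far_blob_matrix
        parts = partition(np.arange(m.n), L=2, R=2, seed_or_rng=1)
        carried = [np.array([0, 1, 2])]
        bucket = fill_bucket(m, parts, CoreParams(k0=3, seed=2), Bucket(carried))
        assert len(bucket) >= 1 + 4  # every chunk holds blob structure
        np.testing.assert_array_equal(bucket.entries[0], carried[0])

    def test_entries_are_subsets_of_their_chunk(self, far_blob_matrix):
        m, _ = far_blob_matrix
        parts = partition(np.arange(m.n), L=2, R=2, seed_or_rng=1)
        bucket = fill_bucket(m, parts, CoreParams(k0=3, seed=2))
        flat_parts = [set(p.tolist()) for rep in parts for p in rep]
        for e in bucket.entries:
            assert sum(set(e.tolist()) <= fp for fp in flat_parts) >= 1


def _spaced_line(start, count, step=0.1):
    return start + step * np.arange(count)


class TestCombine:
    def make_matrix(self, *segments):
        pts = np.concatenate(segments)[:, None]
        return ExpressionMatrix(pts)

    def test_far_apart_entries_unchanged(self):
        # three dense 1-D segments separated by huge gaps: pi = 0 everywhere
        a = _spaced_line(0.0, 11)
        b = _spaced_line(100.0, 11)
        c = _spaced_line(200.0, 11)
        m = self.make_matrix(a, b, c)
        bucket = Bucket([np.arange(11), np.arange(11, 22), np.arange(22, 33)])
        out = combine(bucket, DecisionRule(kind="mst"), m)
        for before, after in zip(bucket.entries, out.entries):
            np.testing.assert_array_equal(before, after)

    def test_all_similar_entries_absorbed_into_first(self, rng):
        # the average/max cross-distance ratio is at most 1, so gamma = 2
        # makes pi identically 1 on nonempty pairs: everything collapses
        # into the first entry
        P = rng.normal(size=(60, 3)) * 0.2
        m = ExpressionMatrix(P)
        e1, e2, e3 = np.arange(0, 30), np.arange(15, 45), np.arange(30, 60)
        out = combine(Bucket([e1, e2, e3]), DecisionRule(kind="distance_ratio", gamma=2.0), m)
        np.testing.assert_array_equal(out.entries[0], np.arange(60))
        assert out.entries[1].size == 0 and out.entries[2].size == 0

    def test_chain_follows_sequential_hand_trace(self):
        # A=[0,1], B=[1.05,2.05], C=[2.10,3.10] at spacing 0.1.
        # pi(A,B)=1 and pi(B,C)=1 (bridges 0.05 < spacing) but pi(A,C)=0
        # (bridge 1.1).  Hand trace of the sequential recursion with bucket
        # order [A, C, B]: i=0 tests C first (no merge: bridge 1.1), then
        # absorbs B; C is never re-tested against the grown A u B, so the
        # final bucket is [A u B, C, empty] -- order matters by design.
        A = _spaced_line(0.0, 11)
        C = _spaced_line(2.10, 11)
        B = _spaced_line(1.05, 11)
        m = self.make_matrix(A, C, B)
        ia, ic, ib = np.arange(11), np.arange(11, 22), np.arange(22, 33)
        out = combine(Bucket([ia, ic, ib]), DecisionRule(kind="mst"), m)
        np.testing.assert_array_equal(out.entries[0], np.sort(np.concatenate([ia, ib])))
        np.testing.assert_array_equal(out.entries[1], ic)
        assert out.entries[2].size == 0
        # with bucket order [A, B, C], A absorbs B and the grown entry then
        # reaches C through the 0.05 bridge: everything merges
        out2 = combine(Bucket([ia, ib, ic]), DecisionRule(kind="mst"), m)
        np.testing.assert_array_equal(out2.entries[0], np.arange(33))

    def test_empty_entries_skipped_and_logged_merges_recorded(self, rng):
        P = rng.normal(size=(20, 2)) * 0.1
        m = ExpressionMatrix(P)
        log = []
        out = combine(
            Bucket([np.arange(10), np.empty(0, int), np.arange(10, 20)]),
            DecisionRule(kind="mst"),
            m,
            log=log,
        )
        assert out.entries[1].size == 0
        assert log and log[0]["i"] == 0 and log[0]["j"] == 2


class TestSelectTightest:
    def test_single_nonempty_entry_selected(self, rng):
        m = ExpressionMatrix(rng.normal(size=(10, 2)))
        got = select_tightest(Bucket([np.empty(0, int), np.array([1, 2, 3])]), TightnessRule(), m)
        assert got is not None and got[0] == 1
        np.testing.assert_array_equal(got[1], [1, 2, 3])

    def test_matches_exhaustive_sigma_sweep(self, rng):
        m = ExpressionMatrix(rng.normal(size=(40, 3)))
        entries = [
            np.sort(rng.choice(40, size=rng.integers(2, 8), replace=False))
            for _ in range(6)
        ]
        rule = TightnessRule("mst_avg_edge")
        got = select_tightest(Bucket(entries), rule, m)
        sigmas = [sigma(e, m, rule) for e in entries]
        assert got[0] == int(np.argmin(sigmas))
        assert got[2] == pytest.approx(min(sigmas))

    def test_singletons_skipped_and_all_empty_signals_none(self, rng):
        m = ExpressionMatrix(rng.normal(size=(5, 2)))
        assert select_tightest(Bucket([np.array([2])]), TightnessRule(), m) is None
        assert select_tightest(Bucket([np.empty(0, int)]), TightnessRule(), m) is None


class TestAdvance:
    def test_selected_rows_removed_everywhere(self, rng):
        m = ExpressionMatrix(rng.normal(size=(20, 2)))
        bucket = Bucket([np.arange(5), np.arange(3, 9), np.arange(15, 20)])
        selected = np.arange(3, 9)
        active, newb = advance(m, np.arange(20), bucket, selected)
        assert not set(selected.tolist()) & set(active.tolist())
        for e in newb.entries:
            assert not set(e.tolist()) & set(selected.tolist())
        np.testing.assert_array_equal(newb.entries[0], [0, 1, 2])
        assert newb.entries[1].size == 0
        np.testing.assert_array_equal(newb.entries[2], np.arange(15, 20))


class TestRun:
    def small_dataset(self, seed=3):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=15, size=(3, 6))
        rows, labels = [], []
        for i, c in enumerate(centers):
            rows.append(c + rng.normal(0, 1.0, size=(150, 6)))
            labels.append(np.full(150, i + 1))
        rows.append(rng.normal(0, np.sqrt(15**2 + 1), size=(30, 6)))
        labels.append(np.zeros(30, dtype=int))
        X = np.vstack(rows)
        lab = np.concatenate(labels)
        perm = rng.permutation(len(lab))
        return ExpressionMatrix(X[perm]), lab[perm]

    def test_disjoint_coverage_and_sigma_order(self):
        m, lab = self.small_dataset()
        res = run(m, 4, plan(m.n, 160, repeats=2), CoreParams(seed=5), seed=5)
        assert res.clusters, "expected at least one cluster"
        flat = np.concatenate(res.clusters)
        assert len(flat) == len(set(flat.tolist()))
        assert len(flat) <= m.n
        np.testing.assert_array_equal(
            np.sort(np.concatenate([flat, res.noise])), np.arange(m.n)
        )
        for rec, s in zip(res.log, res.sigmas):
            assert rec["selected_sigma"] == pytest.approx(s)

    def test_fixed_seed_reproduces_byte_identical_result(self):
        m, _ = self.small_dataset()
        r1 = run(m, 3, plan(m.n, 160, repeats=2), CoreParams(seed=9), seed=9)
        r2 = run(m, 3, plan(m.n, 160, repeats=2), CoreParams(seed=9), seed=9)
        assert len(r1.clusters) == len(r2.clusters)
        for a, b in zip(r1.clusters, r2.clusters):
            assert a.tobytes() == b.tobytes()
        assert r1.noise.tobytes() == r2.noise.tobytes()
        assert r1.sigmas == r2.sigmas

    def test_blobs_recovered_with_early_termination_allowed(self):
        m, lab = self.small_dataset(seed=11)
        res = run(m, 6, plan(m.n, 160, repeats=2), CoreParams(seed=11), seed=11)
        assert len(res.clusters) <= 6
        # blobs may split across extractions (residual cores re-extracted
        # later), but every output cluster must be pure and most of each
        # blob must end up clustered rather than in noise
        pred = res.labels(m.n)
        for c in res.clusters:
            counts = np.bincount(lab[c], minlength=4)
            assert counts.max() >= 0.9 * c.size
        for blob in (1, 2, 3):
            members = pred[lab == blob]
            assert (members > 0).sum() >= 0.6 * members.size

    def test_degenerate_plan_single_chunk_single_repeat(self, blob_builder, rng):
        m, _ = blob_builder(rng, [[0] * 5, [20] * 5], [40, 40], 0.5)
        p = plan(m.n, m.n, repeats=1)  # L = 1, R = 1: one core run
        res = run(m, 1, p, CoreParams(seed=2), seed=2)
        assert len(res.clusters) <= 1
        if res.clusters:
            assert res.clusters[0].size >= 2

    def test_concordance_trend_in_repetitions(self):
        # two rows planted in the tightest blob should land in the same
        # output cluster more often as R grows (R = 1 vs 3, pooled seeds)
        hits = {1: 0, 3: 0}
        trials = 6
        for R in hits:
            for seed in range(trials):
                m, lab = self.small_dataset(seed=20 + seed)
                pair = np.flatnonzero(lab == 1)[:2]
                res = run(m, 3, plan(m.n, 160, repeats=R), CoreParams(seed=seed), seed=seed)
                pred = res.labels(m.n)
                if pred[pair[0]] == pred[pair[1]] != 0:
                    hits[R] += 1
        assert hits[3] >= hits[1]
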