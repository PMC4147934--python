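import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import prosig as ps
from prosig.scoring import WalkWeights


def brute_force_walk(membership, d_in, d_out):
    """Independent oracle: explicit partial-sum enumeration."""
    total, best, worst = 0.0, -np.inf, np.inf
    for in_set in membership:
        total += d_in if in_set else d_out
        best = max(best, total)
        worst = min(worst, total)
    return best, worst


class TestWalk:
    @pytest.mark.parametrize(
        "ranks,expected",
        [
            ({0, 1}, (2.0, 0.0, 2.0)),  # set at top: sums 1,2,1,0
            ({2, 3}, (0.0, -2.0, 2.0)),  # set at bottom: sums -1,-2,-1,0
            ({0, 2}, (1.0, 0.0, 1.0)),  # alternating: sums 1,0,1,0
        ],
    )
    def test_hand_enumerated_four_gene_walks(self, ranks, expected):
        membership = [i in ranks for i in range(4)]
        w = WalkWeights("zero_sum_ks", 4, 2)
        assert (w.d_in, w.d_out) == (1.0, -1.0)
        scores = ps.gsea_walk(membership, w)
        assert (scores.positive, scores.negative, scores.total) == expected

    def test_literal_variant_increments(self):
        w = WalkWeights("literal", 4, 1)
        assert w.d_in == pytest.approx(3.0)
        assert w.d_out == pytest.approx(-1.0 / 3.0)
        scores = ps.gsea_walk([True, False, False, False], w)
        assert scores.positive == pytest.approx(3.0)
        assert scores.negative == pytest.approx(2.0)  # literal walk ends at N-2S side

    def test_degenerate_set_sizes_rejected(self):
        with pytest.raises(ValueError, match="1 <= S < N"):
            WalkWeights("zero_sum_ks", 4, 0)
        with pytest.raises(ValueError, match="1 <= S < N"):
            WalkWeights("zero_sum_ks", 4, 4)

    @pytest.mark.parametrize("variant", ["zero_sum_ks", "literal"])
    def test_matches_brute_force_oracle_exhaustively(self, variant):
        for N in range(2, 7):
            for S in range(1, min(4, N - 1) + 1):
                w = WalkWeights(variant, N, S)
                for ranks in itertools.combinations(range(N), S):
                    membership = [i in ranks for i in range(N)]
                    scores = ps.gsea_walk(membership, w)
                    best, worst = brute_force_walk(membership, w.d_in, w.d_out)
                    assert scores.positive == pytest.approx(best)
                    assert scores.negative == pytest.approx(worst)

    @given(
        N=st.integers(4, 60),
        data=st.data(),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_zero_sum_variant_terminates_at_zero(self, N, data):
        S = data.draw(st.integers(1, N - 1))
        ranks = data.draw(
            st.sets(st.integers(0, N - 1), min_size=S, max_size=S)
        )
        w = WalkWeights("zero_sum_ks", N, S)
        steps = np.where([i in ranks for i in range(N)], w.d_in, w.d_out)
        assert abs(np.cumsum(steps)[-1]) < 1e-9
        scores = ps.gsea_walk([i in ranks for i in range(N)], w)
        assert scores.positive >= -1e-12 >= -abs(scores.negative) - 1e-12
        assert scores.total >= max(scores.positive, -scores.negative) - 1e-12

    def test_complement_symmetry_at_half_membership(self):
        # S = N/2 makes d_in = -d_out, so a set and its complement walk
        # mirror each other and share the same total.
        rng = np.random.default_rng(0)
        N = 20
        w = WalkWeights("zero_sum_ks", N, N // 2)
        for _ in range(25):
            membership = np.zeros(N, dtype=bool)
            membership[rng.choice(N, N // 2, replace=False)] = True
            a = ps.gsea_walk(membership, w)
            b = ps.gsea_walk(~membership, w)
            assert a.total == pytest.approx(b.total)


def _matrix(values, genes, samples):
    return ps.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _sets(*members):
    return ps.GeneSetCollection(
        [ps.GeneSet(f"S{i}", frozenset(m)) for i, m in enumerate(members, 1)]
    )


class TestRawScores:
    def setup_method(self):
        rng = np.random.default_rng(42)
        self.genes = [f"g{i}" for i in range(30)]
        self.samples = [f"s{j}" for j in range(6)]
        self.X = _matrix(rng.normal(size=(30, 6)), self.genes, self.samples)
        self.coll = _sets(self.genes[:8], self.genes[10:18])

    def test_constant_gene_offset_leaves_scores_unchanged(self):
        shifted = self.X.data.copy()
        shifted.loc["g3"] += 100.0
        a = ps.compute_raw_scores(self.X, self.coll)
        b = ps.compute_raw_scores(_matrix(shifted, self.genes, self.samples), self.coll)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_permutation_permutes_columns(self):
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        a = ps.compute_raw_scores(self.X, self.coll)
        b = ps.compute_raw_scores(
            ps.ExpressionMatrix(self.X.data[perm]), self.coll
        )
        pd.testing.assert_frame_equal(a[perm], b)

    def test_centering_is_idempotent(self):
        # scoring a pre-centered matrix reproduces the original scores
        a = ps.compute_raw_scores(self.X, self.coll)
        centered = self.X.data.sub(self.X.data.mean(axis=1), axis=0)
        c = ps.compute_raw_scores(
            _matrix(centered.to_numpy(), self.genes, self.samples), self.coll
        )
        pd.testing.assert_frame_equal(a, c)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_rank_invariance_under_monotone_transform(self, seed):
        # the walk consumes only each sample's ranking of centered values:
        # any strictly increasing transform leaves the scores unchanged
        rng = np.random.default_rng(seed)
        v = rng.normal(size=25)
        membership = np.zeros(25, dtype=bool)
        membership[rng.choice(25, 6, replace=False)] = True
        w = WalkWeights("zero_sum_ks", 25, 6)
        order = np.argsort(-v, kind="stable")
        warped = np.exp(v) + 3.0 * v  # strictly increasing
        order_w = np.argsort(-warped, kind="stable")
        assert np.array_equal(order, order_w)
        assert ps.gsea_walk(membership[order], w) == ps.gsea_walk(membership[order_w], w)

    def test_top_block_sample_matches_direct_walk(self):
        genes = [f"g{i}" for i in range(12)]
        vals = np.zeros((12, 2))
        vals[:, 1] = np.linspace(1, -1, 12)  # sample s1 ranks g0..g11 descending
        vals[:4, 1] += 5.0  # set genes pinned to the top in s1
        X = _matrix(vals + np.random.default_rng(1).normal(0, 1e-6, (12, 2)), genes, ["s0", "s1"])
        coll = _sets(genes[:4])
        raw = ps.compute_raw_scores(X, coll)
        w = WalkWeights("zero_sum_ks", 12, 4)
        direct = ps.gsea_walk([True] * 4 + [False] * 8, w)
        assert raw.loc["S1", "s1"] == pytest.approx(direct.total)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ps.compute_raw_scores(self.X, ps.GeneSetCollection([]))


class TestReduce:
    def test_group_averaging(self):
        raw = pd.DataFrame(
            {"x": [0.2, 0.4, 0.5]}, index=["A", "B", "C"]
        )
        out = ps.reduce_related_sets(raw, {"M1": ["A", "B"], "M2": ["C"]})
        assert out.loc["M1", "x"] == pytest.approx(0.3)
        assert out.loc["M2", "x"] == pytest.approx(0.5)
        assert list(out.index) == ["M1", "M2"]

    def test_ungrouped_sets_pass_through_after_groups(self):
        raw = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["A", "B", "C"])
        out = ps.reduce_related_sets(raw, {"M": ["B"]})
        assert list(out.index) == ["M", "A", "C"]
        assert out.loc["A", "x"] == 1.0

    def test_identity_mapping(self):
        raw = pd.DataFrame({"x": [1.0, 2.0]}, index=["A", "B"])
        pd.testing.assert_frame_equal(ps.reduce_related_sets(raw, None), raw)

    def test_unknown_set_rejected(self):
        raw = pd.DataFrame({"x": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="X"):
            ps.reduce_related_sets(raw, {"M": ["A", "X"]})

    def test_set_in_two_groups_rejected(self):
        raw = pd.DataFrame({"x": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="more than one group"):
            ps.reduce_related_sets(raw, {"M1": ["A"], "M2": ["A", "B"]})


class TestNormalize:
    def test_per_sample_minmax(self):
        raw = pd.DataFrame({"s": [2.0, 4.0, 6.0]}, index=list("abc"))
        out = ps.normalize_signatures(raw, "per_sample")
        assert list(out["s"]) == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_half_with_warning(self):
        raw = pd.DataFrame({"s": [3.0, 3.0, 3.0], "t": [1.0, 2.0, 3.0]}, index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            out = ps.normalize_signatures(raw, "per_sample")
        assert list(out["s"]) == [0.5, 0.5, 0.5]
        assert list(out["t"]) == [0.0, 0.5, 1.0]

    def test_per_set_spans_rows(self):
        raw = pd.DataFrame(
            [[1.0, 3.0, 2.0], [5.0, 0.0, 10.0]], index=["a", "b"], columns=list("xyz")
        )
        out = ps.normalize_signatures(raw, "per_set")
        assert out.loc["a"].min() == 0.0 and out.loc["a"].max() == 1.0
        assert out.loc["b", "z"] == 1.0

    def test_random_set_pvalue_add_one_smoothing(self):
        # a set pinned to the exact top of one sample's centered ranking
        # beats every size-matched random set there: p = 1 / (B + 1)
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        vals = rng.normal(size=(40, 3))
        vals[:4, 0] += 50.0  # upregulated in s0 only (survives centering)
        X = _matrix(vals, genes, ["s0", "s1", "s2"])
        coll = _sets(genes[:4])
        raw = ps.compute_raw_scores(X, coll)
        out = ps.normalize_signatures(
            raw, "random_set_pvalue", expression=X, sets=coll, n_random_sets=99, rng=11
        )
        assert out.loc["S1", "s0"] == pytest.approx(1.0 / 100.0)

    def test_random_set_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        X = _matrix(rng.normal(size=(30, 4)), genes, list("abcd"))
        coll = _sets(genes[:6], genes[6:12])
        raw = ps.compute_raw_scores(X, coll)
        out = ps.normalize_signatures(
            raw, "random_set_pvalue", expression=X, sets=coll, n_random_sets=49, rng=0
        )
        arr = out.to_numpy()
        assert np.all(arr > 0.0) and np.all(arr <= 1.0)

    def test_unknown_mode_rejected(self):
        raw = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="mode"):
            ps.normalize_signatures(raw, "zscore")
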