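"""Memory fitting, similarity, top-n aggregation, decision and explanation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nsbc import (
    NSBCModel,
    class_scores,
    decide,
    explain,
    fit,
    fit_nsbc,
    hamming,
    similarity_vector,
)
from nsbc.fixtures import make_worked_example
from nsbc.rbc import bits_to_str


def naive_hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


class TestHamming:
    def test_worked_pair(self):
        assert hamming("110010", "101111") == 4

    def test_identity_and_complement(self):
        s = "10110100"
        assert hamming(s, s) == 0
        comp = "".join("1" if c == "0" else "0" for c in s)
        assert hamming(s, comp) == len(s)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            hamming("101", "10")

    @given(st.integers(min_value=0, max_value=2**64 - 1), st.integers(min_value=0, max_value=2**64 - 1))
    def test_against_naive_loop_oracle(self, a, b):
        sa, sb = format(a, "064b"), format(b, "064b")
        assert hamming(sa, sb) == naive_hamming(sa, sb)


class TestFit:
    def test_worked_example_memory(self, worked_example):
        m = worked_example.memory()
        assert m.class_names == ("A", "B")
        assert m.class_counts == (2, 3)
        assert m.k_min == 2
        assert m.u == 6

    def test_single_pattern_per_class(self):
        m = fit(["01", "10"], ["x", "y"])
        assert m.k_min == 1

    def test_errors(self):
        with pytest.raises(ValueError):
            fit(["01", "10"], ["only", "only"])  # one class
        with pytest.raises(ValueError):
            fit(["01", "100"], ["a", "b"])  # ragged lengths

    def test_row_permutation_invariance(self, worked_example):
        m = worked_example.memory()
        rng = np.random.default_rng(0)
        perm = rng.permutation(5)
        m2 = fit(
            [worked_example.encoded[i] for i in perm],
            [worked_example.labels[i] for i in perm],
            profile=worked_example.profile,
        )
        assert m2.class_counts == m.class_counts
        for q in ("110010", "000000", "111111"):
            a = class_scores(similarity_vector(m, q), m, 2)
            b = class_scores(similarity_vector(m2, q), m2, 2)
            assert a.scores == b.scores and a.predicted == b.predicted


class TestSimilarity:
    def test_worked_example_vector(self, worked_example):
        sv = similarity_vector(worked_example.memory(), worked_example.query_bits)
        assert sv.z.tolist() == list(worked_example.expected_z)

    def test_stored_pattern_scores_u(self, worked_example):
        m = worked_example.memory()
        sv = similarity_vector(m, worked_example.encoded[0])
        assert sv.z[0] == m.u

    @given(st.integers(min_value=0, max_value=2**20))
    def test_conservation_z_plus_h_equals_u(self, seed):
        m = make_worked_example().memory()
        rng = np.random.default_rng(seed)
        q = rng.integers(0, 2, size=m.u).astype(np.uint8)
        sv = similarity_vector(m, q)
        for mu in range(m.n_patterns):
            assert sv.z[mu] + hamming(q, m.bits[mu]) == m.u


class TestScoresAndDecision:
    def test_worked_example_scores(self, worked_example):
        m = worked_example.memory()
        cs = class_scores(similarity_vector(m, worked_example.query_bits), m, worked_example.n)
        assert dict(zip(m.class_names, cs.scores)) == worked_example.expected_scores
        assert cs.onehot == worked_example.expected_onehot
        assert m.class_names[cs.predicted] == worked_example.expected_class

    def test_n_clamps_to_class_size(self, worked_example):
        m = worked_example.memory()
        cs = class_scores(similarity_vector(m, worked_example.query_bits), m, 10)
        # degenerate top-n: every z in the class is summed
        assert cs.scores == (6, 12)
        assert cs.n_used == (2, 3)

    @given(st.lists(st.integers(min_value=0, max_value=6), min_size=5, max_size=5), st.integers(1, 4))
    def test_topn_matches_sort_oracle(self, zvals, n):
        fx = make_worked_example()
        m = fx.memory()
        sv = similarity_vector(m, fx.query_bits)
        sv.z = np.asarray(zvals)
        cs = class_scores(sv, m, n)
        for i in range(2):
            mine = sorted(np.asarray(zvals)[m.class_positions(i)], reverse=True)
            assert cs.scores[i] == sum(mine[: min(n, len(mine))])

    def test_decide_tie_marks_all_and_takes_lowest(self):
        pred, onehot = decide([7, 7, 3])
        assert onehot == (1, 1, 0) and pred == 0

    def test_duplicating_majority_patterns_beyond_topn_is_inert(self, worked_example):
        # the imbalance argument: extra copies of class-B patterns cannot
        # raise B's top-2 score once the two best matches are present
        base = worked_example.memory()
        extra = fit(
            list(worked_example.encoded) + ["000010"] * 10,
            list(worked_example.labels) + ["B"] * 10,
        )
        q = worked_example.query_bits
        s1 = class_scores(similarity_vector(base, q), base, 2).scores
        s2 = class_scores(similarity_vector(extra, q), extra, 2).scores
        assert s1 == s2 == (6, 9)

    def test_score_bounds(self, worked_example):
        m = worked_example.memory()
        rng = np.random.default_rng(11)
        for _ in range(20):
            q = rng.integers(0, 2, size=m.u).astype(np.uint8)
            cs = class_scores(similarity_vector(m, q), m, 2)
            for score, used in zip(cs.scores, cs.n_used):
                assert 0 <= score <= used * m.u


class TestEndToEnd:
    def test_worked_example_prediction(self, worked_example):
        m = worked_example.memory()
        cs = class_scores(similarity_vector(m, worked_example.query_bits), m, 2)
        assert m.class_names[cs.predicted] == "B"

    def test_n1_equals_hamming_nearest_neighbour(self, separable_table):
        model = fit_nsbc(separable_table, n=1)
        m = model.memory
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(40):
            q = rng.integers(0, 2, size=m.u).astype(np.uint8)
            sv = similarity_vector(m, q)
            best = np.flatnonzero(sv.z == sv.z.max())
            if len(best) > 1:
                continue  # 1-NN equivalence is claimed for unique maxima only
            cs = class_scores(sv, m, 1)
            assert cs.predicted == m.labels[best[0]]
            checked += 1
        assert checked > 5

    def test_training_record_predicts_own_class(self, separable_table):
        model = fit_nsbc(separable_table, n=1)
        pred = model.predict_table(separable_table.take(range(10)))
        assert list(pred) == list(separable_table.labels[:10])

    def test_batch_equals_rowwise(self, separable_table):
        model = fit_nsbc(separable_table, n=3)
        sub = separable_table.take(range(8))
        batch = model.predict_table(sub)
        rowwise = [model.predict_table(sub.take([i]))[0] for i in range(8)]
        assert list(batch) == rowwise

    def test_relabeling_classes_permutes_predictions(self, worked_example):
        m = worked_example.memory()
        swapped = fit(
            list(worked_example.encoded),
            ["Z" if t == "A" else "Y" for t in worked_example.labels],
        )
        q = worked_example.query_bits
        a = class_scores(similarity_vector(m, q), m, 2)
        b = class_scores(similarity_vector(swapped, q), swapped, 2)
        assert m.class_names[a.predicted] == "B"
        assert swapped.class_names[b.predicted] == "Y"  # the old B

    def test_model_json_roundtrip_is_bit_exact(self, tmp_path, separable_table):
        model = fit_nsbc(separable_table, n=3)
        path = tmp_path / "model.json"
        model.save(str(path))
        loaded = NSBCModel.load(str(path))
        assert (loaded.memory.bits == model.memory.bits).all()
        assert loaded.profile == model.profile
        sub = separable_table.take(range(12))
        assert list(loaded.predict_table(sub)) == list(model.predict_table(sub))


class TestExplanation:
    def test_worked_example_report(self, worked_example):
        ex = explain(worked_example.memory(), worked_example.query_bits, 2)
        assert ex.predicted == "B"
        by_index = {e.index: e for entries in ex.per_class.values() for e in entries}
        assert by_index[0].z == 2 and by_index[0].match_vector == "100010"
        assert by_index[4].z == 5 and by_index[4].match_vector == "111101"
        assert ex.scores == {"A": 6, "B": 9}
        assert ex.margin == 3
        text = ex.render()
        assert "110010" in text and "predicted  : B" in text

    def test_match_vectors_against_fixture(self, worked_example):
        m = worked_example.memory()
        q = np.asarray([int(c) for c in worked_example.query_bits], dtype=np.uint8)
        for mu, expected in enumerate(worked_example.expected_match_vectors):
            got = bits_to_str((m.bits[mu] == q).astype(np.uint8))
            assert got == expected

    def test_segment_matches_sum_to_z(self, worked_example):
        m = worked_example.memory()
        rng = np.random.default_rng(2)
        for _ in range(10):
            q = rng.integers(0, 2, size=m.u).astype(np.uint8)
            ex = explain(m, q, 2)
            for entries in ex.per_class.values():
                for e in entries:
                    assert sum(e.segment_matches) == e.z

    def test_query_equal_to_stored_pattern(self, worked_example):
        m = worked_example.memory()
        ex = explain(m, worked_example.encoded[4], 1)
        entry = [e for e in ex.per_class["B"] if e.index == 4][0]
        assert entry.segment_matches == (3, 3)  # full segment widths
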