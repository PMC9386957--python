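"""Class-specific factorization algorithms, dispatcher, and gen(e) tracking."""

import itertools

import pytest

import tanglefold as tf
from tanglefold import (
    FactorList,
    HeuristicError,
    T,
    TangleClass,
    U,
    bfs_minimal_word,
    classify,
    compose,
    compose_factors,
    crossing_number,
    enumerate_tangles,
    ernst_factorize,
    factorize,
    factorize_raw,
    format_invariant,
    heuristic1_step,
    heuristic2_step,
    identity,
    merge_hook,
    parse_invariant,
    prime,
    score_shrink_locations,
    sort_transversals,
    track_generators,
)
from tanglefold.synth import SyntheticConfig, random_tangle


class TestSortTransversals:
    def test_bubble_sort_display(self):
        # bottom row 1' 2' 4' 3' 7' 6' 5' sorts with swaps at 3, 5, 6, 5
        x = parse_invariant("1:1',2:2',3:4',4:3',5:7',6:6',7:5'")
        assert sort_transversals(x) == FactorList(7, (T(3), T(5), T(6), T(5)))

    def test_identity_and_single_inversion(self):
        assert sort_transversals(identity(4)) == FactorList(4)
        assert sort_transversals(parse_invariant("1:2',2:1'")) == FactorList(2, (T(1),))

    def test_length_equals_crossings_and_composes_back(self):
        perms = itertools.permutations(range(1, 6))
        for p in perms:
            x = tf.Tangle.from_pairs(5, [(k + 1, -v) for k, v in enumerate(p)])
            w = sort_transversals(x)
            assert len(w) == crossing_number(x)
            assert compose_factors(w) == x

    def test_rejects_hooks(self):
        with pytest.raises(ValueError):
            sort_transversals(prime("U", 1, 3))


class TestErnst:
    @pytest.mark.parametrize("i, n", [(1, 2), (2, 4), (5, 6)])
    def test_prime_is_its_own_word(self, i, n):
        assert ernst_factorize(prime("U", i, n)) == FactorList(n, (U(i),))

    def test_worked_small_cases(self):
        assert ernst_factorize(parse_invariant("1:2,3:1',2':3'")) == FactorList(3, (U(1), U(2)))
        assert ernst_factorize(parse_invariant("1:2,1':2'")) == FactorList(2, (U(1),))
        # non-commuting order matters: U_2 . U_1 reverses the reading
        x = compose(prime("U", 2, 3), prime("U", 1, 3))[0]
        assert ernst_factorize(x) == FactorList(3, (U(2), U(1)))

    def test_minimal_on_all_crossing_free_tangles(self):
        for n in (2, 3, 4, 5):
            for x in enumerate_tangles(n):
                if crossing_number(x) or classify(x) is TangleClass.T_TANGLE:
                    continue
                w = ernst_factorize(x)
                assert compose_factors(w) == x
                assert len(w) == tf.minimal_length(x)
                assert w.count_kind("T") == 0

    def test_rejects_crossed_input(self):
        with pytest.raises(ValueError):
            ernst_factorize(prime("T", 1, 2))


class TestMergeHook:
    def test_upper_hook_merge_worked_example(self, trna_tangle):
        merged = merge_hook(trna_tangle, (-2, -3), (2, 4))
        assert format_invariant(merged) == "1:1',2:2',3:5',4:3',5:4'"
        assert merged == compose_factors(FactorList(5, (T(3), T(4))))

    def test_minimal_case(self):
        assert merge_hook(prime("U", 1, 2), (-1, -2), (1, 2)).is_identity()

    def test_any_edge_yields_valid_matching(self, trna_tangle):
        for e in trna_tangle.edges:
            if e != (-2, -3):
                merged = merge_hook(trna_tangle, (-2, -3), e)
                assert len(merged.edges) == trna_tangle.n  # validity via constructor

    def test_requires_size_one_lower_hook(self, big_hook_tangle):
        with pytest.raises(ValueError):
            merge_hook(big_hook_tangle, (-2, -7), (1, 2))


class TestHeuristic1:
    def test_trna_step(self, trna_tangle):
        reduced, yielded = heuristic1_step(trna_tangle)
        assert yielded == U(2)
        assert format_invariant(reduced) == "1:1',2:2',3:5',4:3',5:4'"
        assert compose(reduced, prime("U", 2, 5))[0] == trna_tangle

    def test_positive_transversal_merge(self):
        # the merge partner 4:1' is a positive transversal; the hook ends swap
        x = parse_invariant("1:2,3:4',4:1',5:7',6:6',7:5',2':3'")
        reduced, yielded = heuristic1_step(x)
        assert yielded == U(2)
        assert format_invariant(reduced) == "1:2,3:4',4:3',5:7',6:6',7:5',1':2'"

    def test_minimal_case(self):
        reduced, yielded = heuristic1_step(prime("U", 1, 2))
        assert reduced.is_identity() and yielded == U(1)

    def test_crossing_preserved_on_random_tangles(self):
        for seed in range(200):
            x = random_tangle(SyntheticConfig(seed=seed, n=7, word_length=9))
            if classify(x) is not TangleClass.U_TANGLE:
                continue
            reduced, _ = heuristic1_step(x)
            assert crossing_number(reduced) == crossing_number(x)


class TestShrinkScores:
    def test_score_table(self, big_hook_tangle):
        scores = score_shrink_locations(big_hook_tangle, (-2, -7))
        assert [s.sum for s in scores] == [0, 0, 2, 4, 2]
        by_edge = {e: d for e, d in scores[0].per_edge_delta.items()}
        assert by_edge == {(3, -3): 1, (7, -4): -1, (6, -5): -1, (5, -6): 1}
        assert str(scores[0].factors) == "T6*T5*T4*T3"
        assert str(scores[3].factors) == "T2*T3*T4*T6"
        assert str(scores[4].factors) == "T2*T3*T4*T5"

    def test_score_count_and_word_lengths(self, big_hook_tangle):
        scores = score_shrink_locations(big_hook_tangle, (-2, -7))
        assert len(scores) == 5
        assert all(len(s.factors) == 4 for s in scores)
        assert all(s.sum == sum(s.per_edge_delta.values()) for s in scores)

    def test_rejects_small_hook(self, trna_tangle):
        with pytest.raises(ValueError):
            score_shrink_locations(trna_tangle, (-2, -3))


class TestHeuristic2:
    def test_worked_step(self, big_hook_tangle):
        shrunk, appended = heuristic2_step(big_hook_tangle)
        assert appended == FactorList(7, (T(3), T(4), T(5), T(6)))
        assert format_invariant(shrunk) == "1:2,3:4',4:1',5:7',6:6',7:5',2':3'"
        assert classify(shrunk) is TangleClass.U_TANGLE
        back = shrunk
        for f in appended:
            back = compose(back, f.tangle(7))[0]
        assert back == big_hook_tangle

    def test_small_big_hook(self):
        x = parse_invariant("1:2,3:2',1':3'")
        assert classify(x) is TangleClass.H_TANGLE
        shrunk, appended = heuristic2_step(x)
        assert classify(shrunk) in (TangleClass.U_TANGLE, TangleClass.TL_TANGLE)
        back = shrunk
        for f in appended:
            back = compose(back, f.tangle(3))[0]
        assert back == x

    def test_contract_on_random_big_hooks(self):
        for seed in range(300):
            x = random_tangle(SyntheticConfig(seed=seed, n=7, word_length=10))
            if classify(x) is not TangleClass.H_TANGLE:
                continue
            shrunk, appended = heuristic2_step(x)
            back = shrunk
            for f in appended:
                back = compose(back, f.tangle(x.n))[0]
            assert back == x


class TestDispatcher:
    def test_worked_examples(self, trna_tangle, trna_word, big_hook_tangle, big_hook_word):
        word, certified, _ = factorize(trna_tangle)
        assert word == trna_word and certified
        word, _, _ = factorize(big_hook_tangle)
        assert word == big_hook_word

    def test_identity(self):
        word, certified, _ = factorize(identity(5))
        assert len(word) == 0 and certified

    def test_soundness_exhaustive_b3(self):
        for x in enumerate_tangles(3):
            assert compose_factors(factorize_raw(x)) == x

    def test_minimality_exhaustive_b4(self):
        for x in enumerate_tangles(4):
            word, _, _ = factorize(x)
            assert compose_factors(word) == x
            assert len(word) == tf.minimal_length(x)

    def test_soundness_random_n8(self):
        for seed in range(500):
            x = random_tangle(SyntheticConfig(seed=seed, n=8, word_length=seed % 13))
            word, _, _ = factorize(x)
            assert compose_factors(word) == x

    def test_t_count_equals_crossings_b4(self):
        for x in enumerate_tangles(4):
            word, _, _ = factorize(x)
            assert word.count_kind("T") == crossing_number(x)


class TestPropositions:
    def test_strand_one_fixed_iff_indices_at_least_two(self):
        # a vertical first strand <=> no factor touches position 1 (both ways)
        for x in enumerate_tangles(4):
            word, _, _ = factorize(x)
            has_vertical = (1, -1) in x.edges
            all_high = all(f.i >= 2 for f in word)
            assert has_vertical == all_high

    def test_crossing_edges_share_a_t_factor(self):
        # over random minimal words: crossing edges share a generating T occurrence
        checked = 0
        for seed in range(250):
            x = random_tangle(SyntheticConfig(seed=seed, n=5, word_length=seed % 9))
            word = bfs_minimal_word(x)
            gm = track_generators(word)
            for e1, e2 in itertools.combinations(x.sorted_edges(), 2):
                if tf.edges_cross(e1, e2, x.n):
                    shared = gm.occurrences(e1) & gm.occurrences(e2)
                    assert any(f.kind == "T" for _, f in shared)
                    checked += 1
        assert checked > 100


class TestGeneratorTracking:
    def test_trna_generator_map(self, trna_word):
        gm = track_generators(trna_word)
        assert gm.factor_set((2, 4)) == {T(3), U(2)}
        assert gm.factor_set((3, -5)) == {T(3), T(4)}
        assert gm.factor_set((5, -4)) == {T(4)}
        assert gm.factor_set((-2, -3)) == {U(2)}
        assert gm.factor_set((1, -1)) == set()

    def test_empty_word(self):
        gm = track_generators(FactorList(4))
        assert all(gm.factor_set((d, -d)) == set() for d in range(1, 5))

    def test_single_u_prime(self):
        gm = track_generators(FactorList(2, (U(1),)))
        assert gm.factor_set((1, 2)) == {U(1)}
        assert gm.factor_set((-1, -2)) == {U(1)}

    def test_every_edge_is_a_key(self):
        for seed in range(50):
            cfg = SyntheticConfig(seed=seed, n=6, word_length=7)
            word = tf.random_word(cfg)
            gm = track_generators(word)
            assert set(gm.edges) == set(compose_factors(word).edges)

    def test_json_form(self, trna_word):
        js = track_generators(trna_word).to_json()
        assert js["2:4"] == ["T3", "U2"]
        assert js["1:1'"] == []
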