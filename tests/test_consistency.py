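"""Agreement statistics: kappa, kappa_max, flip distance, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from error_consistency.consistency import (
    AlignmentError,
    BinaryOutcomePair,
    ContingencyCounts,
    UndefinedKappaError,
    agreement_result,
    bootstrap_kappa,
    cohens_kappa,
    count_contingency,
    expected_agreement,
    flips_to_kappa_max,
    kappa_max,
    pairwise_kappa_matrix,
    stability_flag,
)
from oracles import (
    all_tables,
    flip_search,
    kappa_direct,
    kappa_max_by_table_enumeration,
    pair_flip_moves,
)

counts_strategy = st.tuples(
    st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
).filter(lambda t: sum(t) >= 1)


class TestContingency:
    def test_one_of_each_cell(self):
        pair = BinaryOutcomePair.from_sequences([1, 1, 0, 0], [1, 0, 1, 0])
        c = count_contingency(pair)
        assert (c.n11, c.n10, c.n01, c.n00) == (1, 1, 1, 1)

    def test_identity_case(self):
        pair = BinaryOutcomePair.from_sequences([1, 0, 1, 0], [1, 0, 1, 0])
        c = count_contingency(pair)
        assert (c.n11, c.n10, c.n01, c.n00) == (2, 0, 0, 2)

    def test_matches_per_trial_tally(self):
        rng = np.random.default_rng(42)
        a, b = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        c = count_contingency(BinaryOutcomePair.from_sequences(a, b))
        tally = {"11": 0, "10": 0, "01": 0, "00": 0}
        for ai, bi in zip(a, b):
            tally[f"{ai}{bi}"] += 1
        assert (c.n11, c.n10, c.n01, c.n00) == (
            tally["11"], tally["10"], tally["01"], tally["00"]
        )

    def test_misalignment_rejected(self):
        with pytest.raises(AlignmentError):
            BinaryOutcomePair.from_sequences([1, 0], [1, 0, 1])
        with pytest.raises(AlignmentError):
            BinaryOutcomePair((0, 0), np.array([1, 0]), np.array([1, 1]))


class TestExpectedAgreement:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((25, 25, 25, 25), 0.5),          # both marginals 0.5
            ((49, 1, 1, 49), 0.5),            # both marginals 0.5
            ((48, 32, 12, 8), 0.56),          # p1=0.8, p2=0.6
        ],
    )
    def test_known_values(self, counts, expected):
        assert expected_agreement(ContingencyCounts(*counts)) == pytest.approx(expected)

    def test_amplification_near_ceiling(self):
        # marginals 0.975 each -> p_e = 0.95125, 1/(1-p_e) ~ 20.5
        c = ContingencyCounts(960, 15, 15, 10)
        p_e = expected_agreement(c)
        assert p_e == pytest.approx(0.95125)
        assert 1.0 / (1.0 - p_e) == pytest.approx(20.512820512)


class TestKappa:
    @pytest.mark.parametrize(
        "counts, expected, digits",
        [
            ((49, 1, 1, 49), 0.96, 2),
            ((49, 1, 1, 50), 0.9604, 4),
            ((96, 1, 1, 1), 0.49, 2),
            ((96, 1, 1, 2), 0.66, 2),
        ],
    )
    def test_worked_examples(self, counts, expected, digits):
        assert round(cohens_kappa(ContingencyCounts(*counts)), digits) == expected

    def test_perfect_agreement(self):
        assert cohens_kappa(ContingencyCounts(2, 0, 0, 2)) == 1.0

    @pytest.mark.parametrize("counts", [(5, 0, 0, 0), (0, 0, 0, 5)])
    def test_degenerate_raises(self, counts):
        with pytest.raises(UndefinedKappaError):
            cohens_kappa(ContingencyCounts(*counts))

    def test_chance_null_monte_carlo(self):
        rng = np.random.default_rng(123)
        n = 100_000
        a = rng.random(n) < 0.7
        b = rng.random(n) < 0.7
        k = cohens_kappa(count_contingency(BinaryOutcomePair.from_sequences(a, b)))
        assert abs(k) < 0.02  # ~3 SE at this n

    @given(counts_strategy)
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_first_principles(self, counts):
        oracle = kappa_direct(*counts)
        c = ContingencyCounts(*counts)
        if oracle is None:
            with pytest.raises(UndefinedKappaError):
                cohens_kappa(c)
        else:
            assert cohens_kappa(c) == pytest.approx(oracle)

    def test_matches_statsmodels(self):
        # independent cross-check: for a 2x2 correct/incorrect table the
        # multi-category chance agreement reduces to the binomial p_e
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        table = np.array([[37.0, 11.0], [8.0, 44.0]])
        ours = cohens_kappa(ContingencyCounts(37, 11, 8, 44))
        assert ours == pytest.approx(float(sm_kappa(table).kappa))


class TestKappaMaxAndFlips:
    def test_equal_marginals_reach_one(self):
        assert kappa_max(ContingencyCounts(49, 1, 1, 49)) == pytest.approx(1.0)

    def test_unequal_marginals_table_enumeration(self):
        # p1=0.8, p2=0.6 at n=100
        c = ContingencyCounts(48, 32, 12, 8)
        assert kappa_max(c) == pytest.approx((0.8 - 0.56) / 0.44)
        assert kappa_max(c) == pytest.approx(kappa_max_by_table_enumeration(48, 32, 12, 8))

    @pytest.mark.parametrize(
        "counts, expected_flips",
        [
            ((2, 0, 0, 2), 0),
            ((96, 1, 1, 1), 2),
            ((5, 3, 1, 1), 2),
        ],
    )
    def test_flip_distance_examples(self, counts, expected_flips):
        assert flips_to_kappa_max(ContingencyCounts(*counts)) == expected_flips

    def test_flip_example_post_state(self):
        # one pair-flip from (5,3,1,1) lands on (6,2,0,2), which attains kappa_max
        assert (6, 2, 0, 2) in pair_flip_moves((5, 3, 1, 1))
        assert kappa_direct(6, 2, 0, 2) == pytest.approx(
            kappa_max(ContingencyCounts(5, 3, 1, 1))
        )

    def test_matches_flip_search_on_small_tables(self):
        # spot sample here; the exhaustive n <= 20 sweep runs in the
        # acceptance suite
        rng = np.random.default_rng(0)
        tables = [t for t in all_tables(12) if kappa_direct(*t) is not None]
        for idx in rng.choice(len(tables), size=80, replace=False):
            t = tables[idx]
            c = ContingencyCounts(*t)
            k_oracle, flips_oracle = flip_search(t)
            assert kappa_max(c) == pytest.approx(k_oracle, abs=1e-10), t
            assert flips_to_kappa_max(c) == flips_oracle, t

    @given(counts_strategy)
    @settings(max_examples=100, deadline=None)
    def test_pair_flips_preserve_both_accuracies(self, counts):
        n = sum(counts)
        c0 = ContingencyCounts(*counts)
        for nxt in pair_flip_moves(counts):
            c1 = ContingencyCounts(*nxt)
            assert c1.n == n
            assert c1.acc_a == pytest.approx(c0.acc_a)
            assert c1.acc_b == pytest.approx(c0.acc_b)

    @given(counts_strategy)
    @settings(max_examples=100, deadline=None)
    def test_kappa_never_exceeds_kappa_max(self, counts):
        c = ContingencyCounts(*counts)
        try:
            k = cohens_kappa(c)
        except UndefinedKappaError:
            return
        assert k <= kappa_max(c) + 1e-12
        assert (flips_to_kappa_max(c) == 0) == (k == pytest.approx(kappa_max(c)))


class TestCeilingInstability:
    def test_one_added_trial_near_ceiling_vs_mid_accuracy(self):
        """A single extra both-incorrect trial barely moves kappa at 50%
        accuracy but jumps it by > 0.15 near ceiling."""
        mid_before = cohens_kappa(ContingencyCounts(49, 1, 1, 49))
        mid_after = cohens_kappa(ContingencyCounts(49, 1, 1, 50))
        ceil_before = cohens_kappa(ContingencyCounts(96, 1, 1, 1))
        ceil_after = cohens_kappa(ContingencyCounts(96, 1, 1, 2))
        assert abs(mid_after - mid_before) <= 0.001
        assert abs(ceil_after - ceil_before) >= 0.15


class TestStability:
    @pytest.mark.parametrize(
        "counts, threshold, stable",
        [
            ((96, 1, 1, 1), 10, False),   # 2 flips < 10
            ((40, 10, 10, 40), 10, True),  # 20 flips >= 10
            ((96, 1, 1, 1), 0, True),      # vacuous threshold
        ],
    )
    def test_threshold(self, counts, threshold, stable):
        assert stability_flag(ContingencyCounts(*counts), threshold) is stable


class TestBootstrap:
    def test_identical_sequences_give_unit_interval(self):
        pair = BinaryOutcomePair.from_sequences([1, 0, 1, 0, 1], [1, 0, 1, 0, 1])
        ci = bootstrap_kappa(pair, n_resamples=200, seed=1)
        assert ci.lower == ci.upper == ci.point == 1.0
        assert ci.n_effective <= 200  # all-same resamples are degenerate

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        pair = BinaryOutcomePair.from_sequences(
            rng.integers(0, 2, 200), rng.integers(0, 2, 200)
        )
        ci1 = bootstrap_kappa(pair, n_resamples=500, seed=99)
        ci2 = bootstrap_kappa(pair, n_resamples=500, seed=99)
        assert (ci1.lower, ci1.upper) == (ci2.lower, ci2.upper)

    def test_interval_width_tracks_sampling_error(self):
        from error_consistency.simulate import PairCouplingSpec, simulate_binary_pair

        spec = PairCouplingSpec(p1=0.7, p2=0.7, kappa_target=0.4, n=500, seed=2)
        pair = simulate_binary_pair(spec)
        ci = bootstrap_kappa(pair, n_resamples=2000, coverage=0.68, seed=3)
        half_width = (ci.upper - ci.lower) / 2
        # independent re-simulation estimate of the sampling SD of kappa-hat
        reps = [
            float(
                cohens_kappa(
                    count_contingency(
                        simulate_binary_pair(
                            PairCouplingSpec(0.7, 0.7, 0.4, 500, seed=100 + r)
                        )
                    )
                )
            )
            for r in range(200)
        ]
        se = float(np.std(reps))
        assert abs(half_width - se) / se < 0.2

    def test_all_degenerate_raises(self):
        pair = BinaryOutcomePair.from_sequences([1, 1, 1], [1, 1, 1])
        with pytest.raises(UndefinedKappaError):
            bootstrap_kappa(pair, n_resamples=50, seed=0)


class TestPairwiseMatrix:
    def test_identical_observers(self):
        obs = {"a": [1, 0, 1, 0], "b": [1, 0, 1, 0]}
        mat, labels, _ = pairwise_kappa_matrix(obs)
        assert mat[0, 1] == mat[1, 0] == 1.0
        assert mat[0, 0] == mat[1, 1] == 1.0

    def test_matches_per_pair_computation(self):
        rng = np.random.default_rng(8)
        obs = {name: rng.integers(0, 2, 8) for name in ("a", "b", "c")}
        mat, labels, results = pairwise_kappa_matrix(obs)
        assert np.allclose(mat, mat.T, equal_nan=True)
        for i, la in enumerate(labels):
            for j in range(i + 1, len(labels)):
                lb = labels[j]
                c = count_contingency(
                    BinaryOutcomePair.from_sequences(obs[la], obs[lb])
                )
                try:
                    expected = cohens_kappa(c)
                    assert mat[i, j] == pytest.approx(expected)
                    assert results[(la, lb)].kappa == pytest.approx(expected)
                except UndefinedKappaError:
                    assert np.isnan(mat[i, j])

    def test_group_mean_excludes_diagonal(self):
        from error_consistency.consistency import group_mean_kappa

        mat = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
        assert group_mean_kappa(mat, [0, 1, 2], [0, 1, 2]) == pytest.approx(0.4)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            pairwise_kappa_matrix({"a": [1, 0, 1], "b": [1, 0]})
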