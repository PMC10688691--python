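import numpy as np
import pytest
from scipy.stats import ks_2samp

from ipdssr import (
    CensoringScheme,
    PFFCSample,
    first_failure_from_groups,
    generate_pffc,
    ipd_cdf,
    ipd_rng,
    parse_scheme,
)


class TestParseScheme:
    def test_table_style_tokens(self):
        s = parse_scheme("(5 * 1, 0 * 19)", k=2)
        assert s.removals == (5,) + (0,) * 19
        assert (s.n_groups, s.m_failures, s.k_per_group) == (25, 20, 2)

    def test_mixed_tokens(self):
        s = parse_scheme("(1 * 2, 0 * 8, 1 * 1, 0 * 7, 1 * 2)", k=2)
        assert len(s.removals) == 20
        assert sum(s.removals) == 5
        assert s.n_groups == 25

    def test_bare_values(self):
        s = parse_scheme("(0, 0)", k=1)
        assert s.removals == (0, 0)
        assert s.n_groups == 2

    @pytest.mark.parametrize("bad", ["(5 *, 0)", "(a, 0)", "( , )", "(1 * 2 * 3)"])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_scheme(bad, k=1)


class TestSchemeInvariants:
    def test_count_conservation_enforced(self):
        with pytest.raises(ValueError):
            CensoringScheme(n_groups=10, k_per_group=1, m_failures=5,
                            removals=(1, 0, 0, 0, 0))

    def test_negative_removals_rejected(self):
        with pytest.raises(ValueError):
            CensoringScheme(n_groups=5, k_per_group=1, m_failures=5,
                            removals=(0, 0, -1, 1, 0))

    def test_sample_length_checked(self):
        s = parse_scheme("(0, 0, 0)", k=1)
        with pytest.raises(ValueError):
            PFFCSample(np.array([1.0, 2.0]), s)

    def test_sample_order_checked(self):
        s = parse_scheme("(0, 0)", k=1)
        with pytest.raises(ValueError):
            PFFCSample(np.array([2.0, 1.0]), s)

    def test_ties_admitted(self):
        s = parse_scheme("(0, 0)", k=1)
        sample = PFFCSample(np.array([1.0, 1.0]), s)
        assert sample.m == 2


class TestFirstFailure:
    def test_minima_sorted(self):
        np.testing.assert_array_equal(
            first_failure_from_groups([[3, 5], [2, 9]]), [2, 3]
        )

    def test_single_group(self):
        np.testing.assert_array_equal(first_failure_from_groups([[4, 1, 7]]), [1])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            first_failure_from_groups([[1.0], []])

    def test_jute_first_failure_list_is_subset_of_full_data(self, jute):
        # every published per-group minimum must be one of the 30 raw values
        assert set(np.round(jute.x_first_failure, 3)) <= set(np.round(jute.x_full, 3))
        assert np.all(np.diff(jute.x_first_failure) >= 0)
        assert jute.x_first_failure[0] == pytest.approx(4.266)
        assert jute.x_first_failure[-1] == pytest.approx(56.239)


class TestGeneratePFFC:
    def test_contract_sorted_length_deterministic(self):
        s = parse_scheme("(5 * 1, 0 * 19)", k=2)
        a = generate_pffc(2.0, s, seed=11)
        b = generate_pffc(2.0, s, seed=11)
        assert len(a.times) == 20
        assert np.all(np.diff(a.times) >= 0)
        np.testing.assert_array_equal(a.times, b.times)

    def test_complete_case_distribution(self):
        # k=1, no removals: marginally an ordered i.i.d. sample
        s = CensoringScheme(n_groups=30, k_per_group=1, m_failures=30,
                            removals=(0,) * 30)
        gen = np.concatenate(
            [generate_pffc(1.5, s, seed=100 + i).times for i in range(300)]
        )
        iid = ipd_rng(9000, 1.5, seed=999)
        assert ks_2samp(gen, iid).pvalue > 1e-3

    def test_first_failure_marginal_min_of_all_items(self):
        # n=5 groups of k=2, m=1, G=(4): the single observation is the
        # minimum of all 10 items, so F*(x) = 1 - (1-F(x))**10
        s = CensoringScheme(n_groups=5, k_per_group=2, m_failures=1, removals=(4,))
        rng = np.random.default_rng(5)
        draws = np.array([generate_pffc(1.0, s, rng).times[0] for _ in range(10_000)])
        u = np.sort(1.0 - (1.0 - ipd_cdf(draws, 1.0)) ** 10)
        d = np.max(np.abs(u - np.arange(1, len(u) + 1) / len(u)))
        assert d < 0.02

    def test_progressive_scheme_against_literal_experiment(self):
        # brute-force oracle: simulate the actual censoring experiment
        # (draw every item, observe group minima, withdraw random groups)
        n, k, m, G = 5, 2, 3, (2, 0, 0)
        s = CensoringScheme(n_groups=n, k_per_group=k, m_failures=m, removals=G)
        rng = np.random.default_rng(17)

        def literal_run():
            groups = [ipd_rng(k, 1.0, rng) for _ in range(n)]
            alive = list(range(n))
            observed = []
            for Gi in G:
                minima = {i: min(groups[i]) for i in alive}
                fail = min(minima, key=minima.get)
                observed.append(minima[fail])
                alive.remove(fail)
                drop = rng.choice(alive, size=Gi, replace=False)
                alive = [i for i in alive if i not in drop]
            return observed

        # compare the distribution of the final (deepest-censored) order statistic
        reps = 4000
        brute = np.array([literal_run()[-1] for _ in range(reps)])
        fast = np.array([generate_pffc(1.0, s, rng).times[-1] for _ in range(reps)])
        assert ks_2samp(brute, fast).pvalue > 1e-3

    def test_count_conservation(self):
        s = parse_scheme("(1, 0, 2, 0)", k=3)
        assert s.m_failures + sum(s.removals) == s.n_groups == 7
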