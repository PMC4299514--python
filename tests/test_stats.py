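"""Rank statistics: exact-permutation Spearman against brute-force
enumeration, partial correlation, BH-FDR step-up, and the drug-response
association summary on planted data."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from warburgflux.stats import (
    bh_fdr,
    partial_spearman,
    response_association,
    spearman_exact,
)


class TestSpearmanExact:
    def test_perfect_monotone_small_n(self):
        res = spearman_exact([1, 2, 3], [1, 2, 3], sidedness="greater")
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 6)  # 1 of 3! orderings
        assert res.method == "exact"

    def test_reversal(self):
        res = spearman_exact([1, 2, 3], [3, 2, 1])
        assert res.rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_n7_matches_brute_force_enumeration(self, seed):
        """Exact p equals direct enumeration over all 5040 permutations."""
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=7), rng.normal(size=7)
        res = spearman_exact(x, y, sidedness="two-sided")
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = 0
        for perm in itertools.permutations(range(7)):
            if abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= abs(obs) - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / math.factorial(7), abs=1e-12)

    def test_monte_carlo_path_seed_deterministic(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=15), rng.normal(size=15)
        a = spearman_exact(x, y, seed=5, n_draws=2000)
        b = spearman_exact(x, y, seed=5, n_draws=2000)
        assert a.method == "montecarlo"
        assert a.p == b.p

    def test_constant_vector_flagged(self):
        res = spearman_exact([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.undefined and math.isnan(res.rho)

    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_permutation_p_valid_under_null(self, alpha):
        """P(p <= alpha) under the null stays within 3 binomial SEs."""
        rng = np.random.default_rng(7)
        reps = 400
        hits = sum(
            spearman_exact(rng.normal(size=6), rng.normal(size=6)).p <= alpha
            for _ in range(reps)
        )
        assert hits / reps <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)


class TestPartialSpearman:
    def test_controlled_away_signal(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=30)
        x = rng.normal(size=30)
        res = partial_spearman(x, z, z, n_draws=500)
        assert abs(res.rho) < 1e-9  # y = z exactly: nothing left to correlate

    def test_independent_control_preserves_rho(self):
        rng = np.random.default_rng(1)
        n = 1000
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n) * 0.7
        z = rng.normal(size=n)
        plain = sps.spearmanr(x, y).statistic
        res = partial_spearman(x, y, z, n_draws=200)
        assert res.rho == pytest.approx(plain, abs=0.05)

    def test_exact_path_small_n(self):
        res = partial_spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4], [2, 1, 4, 3, 5])
        assert res.method == "exact"
        assert 0 < res.p <= 1


class TestBHFDR:
    def test_manual_step_up(self):
        mask, adj = bh_fdr([0.01, 0.02, 0.04], alpha=0.05)
        assert mask.all()  # 0.01<=0.0167, 0.02<=0.0333, 0.04<=0.05

    def test_nothing_significant(self):
        mask, _ = bh_fdr([0.5, 0.6, 0.9], alpha=0.05)
        assert not mask.any()

    def test_single_p_at_alpha_boundary(self):
        mask, adj = bh_fdr([0.05], alpha=0.05)
        assert mask.all() and adj[0] == pytest.approx(0.05)

    def test_never_more_discoveries_than_raw_threshold(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(0.001, 1, 50)
            mask, _ = bh_fdr(p, alpha=0.05)
            assert mask.sum() <= (p <= 0.05).sum()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(9)
    lines = [f"L{i}" for i in range(20)]
    w = pd.Series(rng.uniform(0, 1, 20), index=lines)
    n_comp, n_planted = 40, 12
    resp = np.vstack(
        [w + rng.normal(0, 0.2, 20) for _ in range(n_planted)]
        + [rng.normal(0, 1, 20) for _ in range(n_comp - n_planted)]
    )
    responses = pd.DataFrame(resp, index=[f"D{i}" for i in range(n_comp)], columns=lines)
    return w, responses, n_planted / n_comp


class TestResponseAssociation:

    def test_planted_fraction_recovered(self, planted):
        w, responses, frac = planted
        summary = response_association(w, responses, n_shuffles=200, seed=0, n_draws=3000)
        assert summary.fraction_significant == pytest.approx(frac, abs=0.10)
        assert summary.fraction_positive_of_significant > 0.9
        assert summary.empirical_p < 0.05

    def test_shuffled_responses_mostly_null(self, planted):
        w, responses, _ = planted
        rng = np.random.default_rng(4)
        shuffled = responses.copy()
        for comp in shuffled.index:
            shuffled.loc[comp] = rng.permutation(shuffled.loc[comp].to_numpy())
        summary = response_association(w, shuffled, n_shuffles=200, seed=0, n_draws=3000)
        assert summary.fraction_significant <= 0.1

    def test_identical_compound_flagged_positive(self, planted):
        w, responses, _ = planted
        responses = responses.copy()
        responses.loc["D000_self"] = w.to_numpy()
        summary = response_association(w, responses, n_shuffles=50, seed=0, n_draws=3000)
        row = summary.per_compound.set_index("compound").loc["D000_self"]
        assert row["significant"] and row["sign"] > 0

    def test_growth_screen_lists_measure_specific_compounds(self, planted):
        w, responses, _ = planted
        rng = np.random.default_rng(5)
        growth = pd.Series(rng.normal(size=len(w)), index=w.index)  # unrelated to w
        summary = response_association(w, responses, growth=growth, n_shuffles=50, seed=0, n_draws=3000)
        # planted compounds track the measure but not this unrelated growth
        assert len(summary.measure_specific_compounds) >= 8

    def test_misaligned_lines_rejected(self, planted):
        w, responses, _ = planted
        with pytest.raises(ValueError):
            response_association(w.iloc[:10], responses, n_shuffles=10)
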