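"""Association statistics against brute-force oracles."""

from itertools import combinations, permutations
from math import comb

import numpy as np
import pandas as pd
import pytest

from amplimeth.simulate import PanelGenParams, simulate_panel
from amplimeth.stats import (
    associate_panel,
    chi_square,
    fisher_exact,
    log10_percent,
    mann_whitney,
    spearman,
)

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation path)
# ---------------------------------------------------------------------------


def spearman_rho_tie_free(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) on ranks, valid without ties."""
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d2 = np.sum((rx - ry) ** 2)
    n = len(x)
    return 1 - 6 * d2 / (n * (n**2 - 1))


def mann_whitney_exact_enum(a, b):
    """Exact two-sided p by enumerating all group assignments of the
    pooled values (tie-free)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.array(us)
    m = n1 * len(b)
    lo = min(u_obs, m - u_obs)
    # the two tails coincide when U sits at the center of the distribution
    return min(1.0, ((us <= lo).sum() + (us >= m - lo).sum()) / len(us))


def fisher_exact_enum(table):
    """Two-sided Fisher p: sum of hypergeometric probabilities of tables
    (with the observed margins) no more probable than the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(a_):
        return comb(r1, a_) * comb(r2, c1 - a_) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(a_)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


# ---------------------------------------------------------------------------


class TestLog10Percent:
    @pytest.mark.parametrize(
        "pct,floor,expected",
        [(100, 0.1, 2.0), (0, 0.1, -1.0), (0.27, 0.1, np.log10(0.27))],
    )
    def test_examples(self, pct, floor, expected):
        assert log10_percent(pct, floor) == pytest.approx(expected)

    def test_bad_floor(self):
        with pytest.raises(ValueError):
            log10_percent(1.0, 0.0)

    def test_floor_only_affects_small_values(self):
        x = np.array([0.0, 0.05, 0.5, 5.0])
        a = log10_percent(x, 0.1)
        assert a[0] == a[1] == -1.0
        assert a[2] == pytest.approx(np.log10(0.5))


class TestSpearman:
    def test_monotone(self):
        assert spearman([1, 2, 3, 4], [2, 4, 6, 8]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).rho == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        # d^2 = (1+1+1+1+0) -> rho = 1 - 24/120 = 0.8
        r = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.rho == pytest.approx(0.8)
        assert r.r_squared == pytest.approx(0.64)

    def test_all_permutations_n5_match_oracle(self):
        x = np.arange(5, dtype=float)
        for perm in permutations(range(5)):
            y = np.array(perm, float)
            if np.ptp(y) == 0:
                continue
            r = spearman(x, y)
            assert r.rho == pytest.approx(spearman_rho_tie_free(x, y))
            assert r.r_squared == pytest.approx(r.rho**2)

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert spearman(x, y).rho == pytest.approx(spearman(y, x).rho)
        assert spearman(np.exp(x), y).rho == pytest.approx(spearman(x, y).rho)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            spearman([1.0, 1.0, 1.0], [1, 2, 3])


class TestMannWhitney:
    def test_complete_separation(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0

    def test_identical_groups_u_half(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(3 * 3 / 2)

    def test_small_exact_example(self):
        # enumeration of all 6 rank assignments: U=1 -> p = 4/6
        r = mann_whitney([1, 3], [2, 4])
        assert r.statistic == 1.0
        assert r.p_value == pytest.approx(2 / 3)

    def test_u_sum_invariant(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(size=5)
        ra = mann_whitney(a, b)
        rb = mann_whitney(b, a)
        assert ra.statistic + rb.statistic == pytest.approx(len(a) * len(b))

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for n1, n2 in [(2, 2), (3, 3), (4, 4), (3, 4)]:
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            r = mann_whitney(a, b)
            assert r.p_value == pytest.approx(mann_whitney_exact_enum(a, b))

    def test_exact_close_to_normal_approximation(self):
        """Calibration: exact and asymptotic p agree within 0.05 for
        tie-free n1=n2=5."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = rng.normal(size=5), rng.normal(size=5)
            exact = mann_whitney(a, b).p_value
            approx = mannwhitneyu(a, b, method="asymptotic").pvalue
            assert abs(exact - approx) < 0.05

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestContingency:
    def test_fisher_examples(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)
        assert fisher_exact([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_fisher_matches_enumeration_sample(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            t = rng.integers(0, 8, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert fisher_exact(t) == pytest.approx(fisher_exact_enum(t))

    def test_fisher_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fisher_exact([[0, 0], [3, 4]])

    def test_chi_square_null(self):
        stat, p = chi_square([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi_square_known_value(self):
        # hand-computed Pearson statistic without continuity correction
        stat, p = chi_square([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3)
        assert 0 < p < 0.05


class TestAssociatePanel:
    def test_noiseless_expression_correlation(self):
        panel = simulate_panel(PanelGenParams(sigma_e=0.0, seed=5))
        rep = associate_panel(panel).set_index("comparison")
        # the log floor ties methylation values below 0.1%, so |rho| can sit
        # marginally under 1 even though the generator is strictly monotone
        assert rep.loc["dr4_methylation_vs_expression", "rho"] == pytest.approx(-1.0, abs=0.05)
        assert rep.loc["dr5_methylation_vs_expression", "rho"] == pytest.approx(-1.0, abs=0.05)

    def test_default_panel_dr4_correlations_negative(self):
        panel = simulate_panel(PanelGenParams(seed=6))
        rep = associate_panel(panel).set_index("comparison")
        for label in ("expression", "rfi", "inhibition"):
            assert rep.loc[f"dr4_methylation_vs_{label}", "rho"] < 0

    def test_shuffled_inhibition_mostly_null(self):
        """Permutation oracle: shuffling inhibition destroys the
        association in >=90% of shuffles."""
        panel = simulate_panel(PanelGenParams(seed=7))
        rng = np.random.default_rng(8)
        n_shuffles = 100
        n_mw_null = 0
        rhos = []
        for _ in range(n_shuffles):
            shuffled = panel.copy()
            shuffled["inhibition_pct"] = rng.permutation(panel.inhibition_pct.to_numpy())
            rep = associate_panel(shuffled).set_index("comparison")
            mw = rep.loc["inhibition_highly_methylated_vs_rest"]
            n_mw_null += mw.p_value > 0.05
            rhos.append(rep.loc["dr4_methylation_vs_inhibition", "rho"])
        assert n_mw_null >= 0.9 * n_shuffles
        assert np.mean(np.abs(rhos)) < 0.3
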