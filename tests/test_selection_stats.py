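import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import binom

from mitoselect import (
    ClassCounts,
    delta_bootstrap,
    fisher_exact_2x2,
    mannwhitney_u,
    mk_delta,
    mutation_load,
    ng86_dnds,
    pnps_downsampling_test,
    pnps_genome_subsampling_test,
    pnps_ratio,
    spearman,
    variance_f_test,
)
from mitoselect.selection_stats import jukes_cantor

from conftest import table2_oracle


class TestPnPsAndDelta:
    @pytest.mark.parametrize(
        "pn,ps,expected", [(28, 51, 0.549), (41, 145, 0.283), (0, 1, 0.000)]
    )
    def test_pnps_ratio(self, pn, ps, expected):
        assert pnps_ratio(ClassCounts(pn, ps)) == pytest.approx(expected, abs=5e-4)

    def test_pnps_undefined_when_ps_zero(self):
        assert pnps_ratio(ClassCounts(3, 0)) is None

    @pytest.mark.parametrize(
        "quad,expected",
        [((28, 51, 141, 1565), 0.836), ((41, 145, 141, 1565), 0.681)],
    )
    def test_delta_point_estimates(self, quad, expected):
        assert mk_delta(ClassCounts(*quad)) == pytest.approx(expected, abs=5e-4)

    def test_delta_zero_at_neutral_expectation(self):
        # Pn/Ps == Dn/Ds exactly
        assert mk_delta(ClassCounts(10, 20, 30, 60)) == pytest.approx(0.0)

    def test_delta_invariant_to_common_scaling(self):
        base = mk_delta(ClassCounts(7, 13, 29, 163))
        scaled = mk_delta(ClassCounts(21, 39, 87, 489))
        assert scaled == pytest.approx(base)

    def test_delta_undefined_cases(self):
        with pytest.raises(ValueError):
            mk_delta(ClassCounts(0, 5, 3, 10))
        with pytest.raises(ValueError):
            mk_delta(ClassCounts(5, 5, 3, 0))


class TestDeltaBootstrap:
    def test_reported_interval_at_study_counts(self):
        est = delta_bootstrap(ClassCounts(28, 51, 141, 1565), n_boot=10_000, seed=42)
        assert est.ci_low == pytest.approx(0.72, abs=0.02)
        assert est.ci_high == pytest.approx(0.90, abs=0.02)
        assert est.ci_low <= est.delta <= est.ci_high

    def test_neutral_case_interval_straddles_zero(self):
        est = delta_bootstrap(ClassCounts(200, 200, 200, 200), n_boot=5_000, seed=1)
        assert est.ci_low < 0 < est.ci_high

    def test_tiny_counts_match_exhaustive_enumeration(self):
        # (2,2,2,2): enumerate every (Pn*, Dn*) binomial outcome exactly
        probs = binom.pmf(np.arange(5), 4, 0.5)
        atoms = []
        for pn, p_pn in enumerate(probs):
            for dn, p_dn in enumerate(probs):
                ps, ds = 4 - pn, 4 - dn
                if pn == 0 or ds == 0:
                    d = -np.inf
                else:
                    d = 1.0 - (dn * ps) / (ds * pn)
                atoms.append((d, p_pn * p_dn))
        atoms.sort()
        values = np.array([a[0] for a in atoms])
        cdf = np.cumsum([a[1] for a in atoms])
        lo_exact = values[np.searchsorted(cdf, 0.025)]
        hi_exact = values[np.searchsorted(cdf, 0.975)]
        est = delta_bootstrap(ClassCounts(2, 2, 2, 2), n_boot=40_000, seed=9)
        assert est.ci_low == lo_exact  # both land on the same atom
        assert est.ci_high == hi_exact

    def test_coverage_at_study_count_magnitudes(self):
        # generate data at the study's true class rates: the 95% percentile
        # interval covers the true delta in ~93% of runs (slight undercoverage
        # is expected for discrete counts); allow two MC standard errors
        rng = np.random.default_rng(2024)
        p_rate, d_rate = 28 / 79, 141 / 1706
        true_delta = 1.0 - (d_rate / (1 - d_rate)) / (p_rate / (1 - p_rate))
        hits = runs = 0
        for _ in range(300):
            pn = int(rng.binomial(79, p_rate))
            dn = int(rng.binomial(1706, d_rate))
            if pn == 0 or dn == 1706:
                continue
            est = delta_bootstrap(
                ClassCounts(pn, 79 - pn, dn, 1706 - dn),
                n_boot=1_000,
                seed=int(rng.integers(2**31)),
            )
            runs += 1
            hits += est.ci_low <= true_delta <= est.ci_high
        target = 0.93
        assert hits / runs >= target - 2 * math.sqrt(target * (1 - target) / runs)


class TestMutationLoad:
    def test_examples(self):
        assert mutation_load(0.5, 2.0) == pytest.approx(1.0)
        assert mutation_load(0.0, 7.3) == 0.0

    def test_delta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            mutation_load(1.2, 1.0)


def fisher_two_sided_oracle(table):
    """Exhaustive margin-preserving enumeration with the point-probability rule."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [([[28, 51], [41, 145]], 0.032), ([[12, 36], [0, 17]], 0.027), ([[1, 1], [1, 1]], 1.0)],
    )
    def test_study_tables(self, table, expected):
        assert fisher_exact_2x2(table).p_value == pytest.approx(expected, abs=5e-4)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 5]]).p_value == 1.0

    def test_matches_exhaustive_enumeration_for_small_margins(self):
        rng = np.random.default_rng(7)
        tables = [rng.integers(0, 16, size=(2, 2)) for _ in range(40)]
        tables += [[[28, 51], [41, 145]], [[12, 36], [0, 17]]]
        for t in tables:
            t = np.asarray(t)
            expected = fisher_two_sided_oracle(t)
            assert fisher_exact_2x2(t).p_value == pytest.approx(expected, rel=1e-9)


class TestDownsamplingTest:
    def test_all_synonymous_source_cannot_exceed(self):
        labels = ["syn"] * 50
        res = pnps_downsampling_test(labels, 20, 0.5, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_study_contrast_is_significant(self):
        labels = ["nonsyn"] * 41 + ["syn"] * 145
        res = pnps_downsampling_test(labels, 79, 28 / 51, n_perm=10_000, seed=0)
        assert res.p_value < 0.05

    def test_super_uniform_under_null(self):
        # observed ratios drawn from the null itself: P(p <= a) <= a (+ MC slack)
        rng = np.random.default_rng(3)
        labels = ["nonsyn"] * 41 + ["syn"] * 145
        pvals = []
        for _ in range(400):
            pn = rng.hypergeometric(41, 145, 79)
            obs = pn / (79 - pn) if pn < 79 else np.inf
            res = pnps_downsampling_test(
                labels, 79, obs, n_perm=1_000, seed=int(rng.integers(2**31))
            )
            pvals.append(res.p_value)
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            assert (pvals <= alpha).mean() <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / 400)

    def test_genome_subsampling_mode_runs(self, sim_default):
        aln, _ = sim_default
        res = pnps_genome_subsampling_test(
            aln, "brackish", 26, 28 / 51, n_perm=200, seed=5
        )
        assert 0 < res.p_value <= 1


def ng86_oracle(codons_a, codons_b, code):
    """Hand NG86 computation for single-difference codon pairs only."""
    S = N = sd = nd = 0.0
    for x, y in zip(codons_a, codons_b):
        for codon in (x, y):
            syn = sum(
                code[codon[:i] + nuc + codon[i + 1 :]] == code[codon]
                for i in range(3)
                for nuc in "ACGT"
                if nuc != codon[i]
            ) / 3.0
            S += syn / 2.0
            N += (3.0 - syn) / 2.0
        if x != y:
            if code[x] == code[y]:
                sd += 1
            else:
                nd += 1
    ds = -0.75 * math.log(1 - 4 * (sd / S) / 3) if sd else 0.0
    dn = -0.75 * math.log(1 - 4 * (nd / N) / 3) if nd else 0.0
    return dn, ds


class TestNG86:
    def test_identical_sequences(self):
        dn, ds, ratio = ng86_dnds([["ATG", "GGA"]], [["ATG", "GGA"]])
        assert (dn, ds, ratio) == (0.0, 0.0, None)

    def test_single_synonymous_difference_matches_hand_computation(self):
        a, b = ["ATG", "GGA", "TTT"], ["ATG", "GGG", "TTT"]
        dn, ds, ratio = ng86_dnds([a], [b])
        dn_o, ds_o = ng86_oracle(a, b, table2_oracle())
        assert dn == pytest.approx(dn_o)
        assert ds == pytest.approx(ds_o)
        assert dn == 0.0

    def test_zero_nonsynonymous_construction(self):
        # all differences synonymous by construction -> dN = 0 exactly
        a = [["GGA", "CTA", "TCC", "ATG"]]
        b = [["GGG", "CTG", "TCT", "ATA"]]
        dn, ds, ratio = ng86_dnds(a, b)
        assert dn == 0.0
        assert ds > 0.0
        assert ratio == 0.0

    def test_jukes_cantor_ceiling(self):
        with pytest.raises(ValueError):
            jukes_cantor(0.75)


def mw_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = sorted(x + y)
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )

    u_obs = u_stat(x, y)
    us = []
    for idx in combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestRankAndCorrelationTests:
    def test_identical_multisets_give_p_one(self):
        res = mannwhitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_small_sample_matches_permutation_enumeration(self):
        x = [1.2, 3.4, 5.1, 7.7]
        y = [0.4, 2.2, 2.9]
        res = mannwhitney_u(x, y)
        assert res.p_value == pytest.approx(mw_exact_oracle(x, y))

    def test_perfect_monotone_spearman(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.statistic == pytest.approx(1.0)

    def test_constant_input_spearman_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_variance_f_test_symmetric_inputs(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        res = variance_f_test(x, x * 1.0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
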