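"""Coverage filtering, summaries, and the differential-methylation test."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from epievolve import methylation_stats as ms
from epievolve.types import MethylationSite


def site(site_id, totals, meth=None, pos=0):
    meth = meth if meth is not None else [t // 2 for t in totals]
    return MethylationSite(site_id, "c1", pos,
                           {f"s{i}": (m, t) for i, (m, t) in enumerate(zip(meth, totals))})


# ---------------------------------------------------------------------------
# Coverage filter
# ---------------------------------------------------------------------------

class TestCoverageFilter:
    def test_sample_below_minimum_removes_site(self):
        kept, rep = ms.filter_by_coverage([site("a", [10, 30, 30])], min_cov=15)
        assert kept == [] and rep.n_removed_low == 1

    def test_uniform_fifteen_x_all_kept_strict_upper(self):
        sites = [site(f"a{i}", [15, 15, 15]) for i in range(10)]
        kept, rep = ms.filter_by_coverage(sites, min_cov=15)
        # the 97.5% quantile of all-15 totals is 15; removal needs strictly >
        assert len(kept) == 10 and rep.quantile_threshold == 15

    def test_matches_brute_force_on_random_sites(self):
        rng = np.random.default_rng(3)
        sites = [site(f"a{i}", [int(x) for x in rng.integers(5, 400, size=6)])
                 for i in range(40)]
        kept, rep = ms.filter_by_coverage(sites, min_cov=15, max_quantile=0.975)
        all_totals = sorted(t for s in sites for (_, t) in s.counts.values())
        thresh = np.quantile(all_totals, 0.975)
        expected = [s.site_id for s in sites
                    if min(t for _, t in s.counts.values()) >= 15
                    and max(t for _, t in s.counts.values()) <= thresh]
        assert [s.site_id for s in kept] == expected
        assert rep.n_removed_low + rep.n_removed_high + rep.n_retained == 40

    def test_empty_input_zeroed_report(self):
        kept, rep = ms.filter_by_coverage([])
        assert kept == [] and rep.n_input == 0 and rep.n_retained == 0


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

class TestSummaries:
    def test_mean_of_per_site_proportions(self):
        sites = [site("a", [10], [5]), site("b", [10], [0]), site("c", [10], [10])]
        assert ms.global_mean_methylation(sites, "s0") == pytest.approx(0.5)

    def test_fully_methylated(self):
        assert ms.global_mean_methylation([site("a", [8], [8])], "s0") == 1.0

    def test_single_site(self):
        assert ms.global_mean_methylation([site("a", [12], [3])], "s0") == 0.25

    def test_pooled_mode_weights_by_coverage(self):
        sites = [site("a", [100], [100]), site("b", [300], [0])]
        assert ms.global_mean_methylation(sites, "s0", method="pooled") == 0.25
        assert ms.global_mean_methylation(sites, "s0") == 0.5

    def test_no_sites_is_error(self):
        with pytest.raises(ValueError):
            ms.global_mean_methylation([], "s0")


class TestCompareMeans:
    def test_identical_values_give_p_one(self):
        means = {f"s{i}": 0.2 for i in range(8)}
        groups = {f"s{i}": ("F0" if i < 4 else "F25") for i in range(8)}
        p, _ = ms.compare_mean_methylation(means, groups)
        assert p == 1.0

    def test_founder_vs_evolved_generation_difference(self):
        # group means/SDs follow the founder-versus-F25 decline scenario
        rng = np.random.default_rng(0)
        means, groups = {}, {}
        for i in range(4):
            means[f"f{i}"] = float(rng.normal(0.254, 0.003)); groups[f"f{i}"] = "F0"
            means[f"e{i}"] = float(rng.normal(0.229, 0.009)); groups[f"e{i}"] = "F25"
        p, tukey = ms.compare_mean_methylation(means, groups)
        assert p < 0.01
        assert float(tukey["p_adj"].iloc[0]) < 0.01

    def test_single_sample_group_is_error(self):
        with pytest.raises(ValueError):
            ms.compare_mean_methylation({"a": 1.0, "b": 2.0, "c": 3.0},
                                        {"a": "g1", "b": "g1", "c": "g2"})

    def test_null_calibration_of_anova(self):
        # exchangeable samples, shuffled labels: rejection near nominal 5%
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            vals = rng.normal(size=12)
            labels = np.repeat(["a", "b", "c"], 4)
            rng.shuffle(labels)
            means = {f"s{i}": float(v) for i, v in enumerate(vals)}
            groups = {f"s{i}": labels[i] for i in range(12)}
            p, _ = ms.compare_mean_methylation(means, groups, tukey=False)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestConversionEfficiency:
    def test_no_failures(self):
        assert ms.conversion_efficiency([(0, 5000)]) == 1.0

    def test_sixteen_per_thousand(self):
        assert ms.conversion_efficiency([(16, 1000)]) == pytest.approx(0.984)

    def test_everything_methylated(self):
        assert ms.conversion_efficiency([(10, 10), (5, 5)]) == 0.0

    def test_zero_calls_is_error(self):
        with pytest.raises(ValueError):
            ms.conversion_efficiency([])


# ---------------------------------------------------------------------------
# Beta-binomial LRT
# ---------------------------------------------------------------------------

def binomial_lrt_oracle(m_a, n_a, m_b, n_b):
    """Closed-form binomial (phi = 0) likelihood-ratio statistic."""
    def ll(m, n):
        m, n = np.sum(m), np.sum(n)
        if m == 0 or m == n:
            return 0.0
        p = m / n
        return m * np.log(p) + (n - m) * np.log(1 - p)
    # per-group totals are sufficient under the binomial model
    l1 = ll(m_a, n_a) + ll(m_b, n_b)
    l0 = ll(np.concatenate([m_a, m_b]), np.concatenate([n_a, n_b]))
    return 2.0 * (l1 - l0)


class TestBetaBinomialLrt:
    def test_no_effect_gives_large_p(self):
        m = np.full(4, 50); n = np.full(4, 100)
        delta, lrt, p = ms.bb_lrt(m, n, m, n)
        assert abs(delta) < 1e-4 and p > 0.5
        delta2, _, p2 = ms.bb_lrt(m, n, m, n, phi=0.05)
        assert abs(delta2) < 1e-4 and p2 > 0.5

    def test_strong_effect_statistic_matches_binomial_oracle(self):
        m_a, n_a = np.full(4, 90), np.full(4, 100)
        m_b, n_b = np.full(4, 10), np.full(4, 100)
        oracle = binomial_lrt_oracle(m_a, n_a, m_b, n_b)
        # with the dispersion pinned at ~0 both fits are binomial, so the
        # statistic equals the closed-form binomial LRT and the chi-square
        # reference drives the p-value far below 1e-6
        delta, lrt, p = ms.bb_lrt(m_a, n_a, m_b, n_b, phi=1e-8)
        assert delta == pytest.approx(0.8, abs=1e-3)
        assert lrt == pytest.approx(oracle, rel=1e-4)
        assert p < 1e-6
        # the per-site variant estimates the dispersion separately under each
        # hypothesis: the null absorbs the gap into phi, so its statistic is
        # smaller, yet the effect stays unambiguous
        delta_s, lrt_s, p_site = ms.bb_lrt(m_a, n_a, m_b, n_b)
        assert delta_s == pytest.approx(0.8, abs=1e-3)
        assert 0 < lrt_s < oracle
        assert p_site < 1e-3

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            ms.bb_lrt(np.array([]), np.array([]), np.array([5]), np.array([10]))

    def test_per_site_variant_calibration(self, design_4v4):
        # standalone test (per-site dispersion, F reference) near nominal
        # level; each null site draws one mean shared by both groups
        rng = np.random.default_rng(11)
        sites = []
        conc = 0.9 / 0.1
        for j in range(240):
            mu = rng.uniform(0.2, 0.8)
            s = MethylationSite(f"n{j}", "c1", j, {})
            for sid, info in design_4v4:
                n = int(rng.poisson(124)) + 1
                p = rng.beta(mu * conc, (1 - mu) * conc)
                s.counts[sid] = (int(rng.binomial(n, p)), n)
            sites.append(s)
        ps = np.array([ms.test_differential_methylation(s, design_4v4, "OWA").p_value
                       for s in sites])
        assert 0.01 <= np.mean(ps < 0.05) <= 0.10

    def test_common_dispersion_recovered(self, design_4v4, bb_site_factory):
        rng = np.random.default_rng(12)
        sites = bb_site_factory(rng, design_4v4, {"OWA": 0.4, "AM": 0.4},
                                phi=0.05, coverage=80, n_sites=400)
        phi_hat = ms.estimate_common_dispersion(sites, design_4v4)
        assert phi_hat == pytest.approx(0.05, abs=0.015)

    def test_power_increases_with_separation(self, design_4v4, bb_site_factory):
        # monotone expected significance as the group gap grows
        rng = np.random.default_rng(13)
        mean_p = []
        for delta in (0.0, 0.15, 0.3):
            sites = bb_site_factory(rng, design_4v4,
                                    {"OWA": 0.3 + delta, "AM": 0.3},
                                    phi=0.05, coverage=124, n_sites=60)
            ps = [ms.test_differential_methylation(s, design_4v4, "OWA", phi=0.05).p_value
                  for s in sites]
            mean_p.append(np.mean(np.log10(ps)))
        assert mean_p[0] > mean_p[1] > mean_p[2]


# ---------------------------------------------------------------------------
# FDR and calls
# ---------------------------------------------------------------------------

def bh_brute_force(p):
    """Textbook step-up: q_i = min over j>=rank(i) of m p_(j) / j, clipped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


class TestFdr:
    def test_single_p_unchanged(self):
        assert ms.adjust_fdr_bh([0.03]) == pytest.approx([0.03])

    def test_hand_worked_example(self):
        np.testing.assert_allclose(ms.adjust_fdr_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(ms.adjust_fdr_bh([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            ms.adjust_fdr_bh([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            p = rng.uniform(size=int(rng.integers(1, 50)))
            np.testing.assert_allclose(ms.adjust_fdr_bh(p), bh_brute_force(p),
                                       atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        q = ms.adjust_fdr_bh(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q_perm = ms.adjust_fdr_bh([p[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)


class TestCalls:
    def make(self, delta, q):
        from epievolve.types import MethylationTestResult
        r = MethylationTestResult("x", delta, 0.001)
        r.q_value = q
        return r

    @pytest.mark.parametrize("delta,q,expected", [
        (0.12, 0.01, True),
        (0.09, 0.0001, False),   # effect-size gate
        (0.10, 0.0001, False),   # strict inequality on delta
        (0.12, 0.05, False),     # strict inequality on q
        (-0.2, 0.01, True),      # sign-symmetric
    ])
    def test_threshold_logic(self, delta, q, expected):
        r = self.make(delta, q)
        sig = ms.call_significant_sites([r])
        assert (r.site_id in sig) is expected
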