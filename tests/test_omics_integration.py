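"""Window construction, randomization tests, pi strata, KS, overlaps."""
import numpy as np
import pytest

from epievolve import omics_integration as oi
from epievolve.types import GenomicWindow, MethylationSite, SnpSite


def snp(chrom, pos):
    return SnpSite(f"{chrom}:{pos}", chrom, pos, {"p": (1, 10)}, 100, "A", "T")


def meth(chrom, pos):
    return MethylationSite(f"m{chrom}:{pos}", chrom, pos, {"s": (1, 10)})


class TestWindows:
    def test_tiling_keeps_trailing_partial_window(self):
        windows, _ = oi.build_and_filter_windows(
            {"c1": 5000}, [snp("c1", i) for i in range(0, 5000, 10)],
            [meth("c1", i) for i in range(5, 5000, 10)],
            window_len=1500, min_snps=5, min_meth=5)
        assert [(w.start, w.end) for w in windows] == \
            [(0, 1500), (1500, 3000), (3000, 4500), (4500, 5000)]
        assert [w.partial for w in windows] == [False, False, False, True]

    def test_window_below_either_minimum_dropped(self):
        snps = [snp("c1", i) for i in range(5)]          # 5 SNPs
        meths = [meth("c1", i) for i in range(10, 14)]   # 4 methylation sites
        windows, rep = oi.build_and_filter_windows({"c1": 1500}, snps, meths)
        assert windows == [] and rep.n_dropped_meth == 1

    def test_membership_matches_brute_force_containment(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            clen = int(rng.integers(2000, 9000))
            L = int(rng.choice([700, 1500, 2500]))
            snps = [snp("c1", int(p)) for p in
                    rng.choice(clen, size=int(rng.integers(20, 120)), replace=False)]
            meths = [meth("c1", int(p)) for p in
                     rng.choice(clen, size=int(rng.integers(20, 120)), replace=False)]
            min_s, min_m = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            windows, _ = oi.build_and_filter_windows(
                {"c1": clen}, snps, meths, L, min_s, min_m)
            got = {w.window_id: (w.snp_ids, w.meth_ids) for w in windows}
            expected = {}
            k = 0
            while k * L < clen:
                start, end = k * L, min((k + 1) * L, clen)
                sset = {s.snp_id for s in snps if start <= s.pos < end}
                mset = {m.site_id for m in meths if start <= m.pos < end}
                if len(sset) >= min_s and len(mset) >= min_m:
                    expected[f"c1:{start}-{end}"] = (sset, mset)
                k += 1
            assert got == expected

    def test_zero_window_length_is_error(self):
        with pytest.raises(ValueError):
            oi.build_and_filter_windows({"c1": 100}, [], [], window_len=0)

    def test_significance_flags_and_halfopen_boundary(self):
        snps = [snp("c1", i) for i in range(5)] + [snp("c1", 1500 + i) for i in range(5)]
        meths = [meth("c1", i) for i in range(5)] + [meth("c1", 1500 + i) for i in range(5)]
        windows, _ = oi.build_and_filter_windows({"c1": 3000}, snps, meths)
        # a site at pos 1500 belongs to the second window, not the first
        oi.flag_window_methylation_significance(
            windows, {"OWA": {"mc1:1500"}, "OW": set()})
        by_id = {w.window_id: w for w in windows}
        assert by_id["c1:0-1500"].sig_meth["OWA"] is False
        assert by_id["c1:1500-3000"].sig_meth["OWA"] is True
        assert by_id["c1:1500-3000"].sig_meth["OW"] is False


class TestRandomizationTest:
    def test_complete_separation_hits_permutation_floor(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([rng.normal(0, 0.001, 50), rng.normal(9, 0.001, 50)])
        labels = np.array([True] * 50 + [False] * 50)
        res = oi.randomization_test(values, labels, n_perm=10_000, seed=1)
        assert res.observed_diff == pytest.approx(9, abs=0.01)
        assert res.n_ge == 0
        assert res.p_value == pytest.approx(1 / 10_001)
        assert res.p_value <= 1e-4

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError):
            oi.randomization_test([1.0, 2.0], [True, True], n_perm=10, seed=0)

    def test_zero_permutations_error(self):
        with pytest.raises(ValueError):
            oi.randomization_test([1.0, 2.0], [True, False], n_perm=0, seed=0)

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=60)
        labels = rng.uniform(size=60) < 0.4
        a = oi.randomization_test(values, labels, n_perm=500, seed=3)
        b = oi.randomization_test(values, labels, n_perm=500, seed=3)
        assert (a.n_ge, a.p_value) == (b.n_ge, b.p_value)
        c = oi.randomization_test(values, labels, n_perm=500, seed=4)
        # a different seed may move the count only by sampling noise
        assert abs(c.n_ge - a.n_ge) < 5 * np.sqrt(500 * 0.5)

    def test_p_value_invariant_to_affine_value_transform(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=40)
        labels = np.array([True] * 15 + [False] * 25)
        base = oi.randomization_test(values, labels, n_perm=400, seed=5)
        for a, b in ((2.5, 0.0), (1.0, 7.0), (0.3, -2.0)):
            res = oi.randomization_test(a * values + b, labels, n_perm=400, seed=5)
            assert res.n_ge == base.n_ge and res.p_value == base.p_value

    def test_null_rejection_rate_near_alpha(self):
        # exchangeable values: one-sided test rejects at about the nominal rate
        rng = np.random.default_rng(10)
        rejections = 0
        n_runs = 300
        for i in range(n_runs):
            values = rng.normal(size=40)
            labels = np.array([True] * 20 + [False] * 20)
            res = oi.randomization_test(values, labels, n_perm=199, seed=int(i))
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / n_runs <= 0.09


class TestReverseAnalysis:
    def make_windows(self):
        rng = np.random.default_rng(11)
        windows = []
        for i in range(40):
            divergent = i < 20
            w = GenomicWindow(f"w{i}", "c1", i * 1500, (i + 1) * 1500)
            # inverse coupling: allele-divergent windows show small
            # methylation change, others large
            w.mean_abs_delta_meth["OWA"] = float(
                rng.normal(0.05 if divergent else 0.25, 0.01))
            windows.append(w)
        return windows, {f"w{i}" for i in range(20)}

    def test_inverse_coupling_gives_positive_observed_diff(self):
        windows, divergent = self.make_windows()
        res = oi.reverse_methylation_by_allele_divergence(
            windows, divergent, "OWA", n_perm=500, seed=2)
        assert res.observed_diff > 0
        assert res.p_value < 0.05

    def test_empty_divergence_set_is_error(self):
        windows, _ = self.make_windows()
        with pytest.raises(ValueError):
            oi.reverse_methylation_by_allele_divergence(
                windows, set(), "OWA", n_perm=10, seed=0)


class TestPiStrata:
    def test_bin_edges_left_closed(self):
        assert oi.assign_pi_bin(0.005) == 1
        assert oi.assign_pi_bin(0.0) == 0
        assert oi.assign_pi_bin(0.0049999) == 0
        assert oi.assign_pi_bin(0.5) == 5

    def test_small_classes_skipped_with_reason(self):
        windows = []
        for i in range(10):
            w = GenomicWindow(f"w{i}", "c1", 0, 1500)
            w.pi["p"] = 0.002
            w.sig_meth["OWA"] = i == 0  # one significant window only
            w.mean_fst[("OWA", 1)] = 0.01
            windows.append(w)
        out = oi.pi_stratified_fst(windows, "OWA", "p", n_perm=10, seed=0)
        assert isinstance(out[0], str) and "skipped" in out[0]

    def test_strong_effect_rejects_in_every_testable_bin(self):
        rng = np.random.default_rng(12)
        windows = []
        for i in range(120):
            w = GenomicWindow(f"w{i}", "c1", 0, 1500)
            w.pi["p"] = float(rng.uniform(0, 0.04))
            sig = i % 2 == 0
            w.sig_meth["OWA"] = sig
            w.mean_fst[("OWA", 1)] = float(rng.normal(0.002 if sig else 0.02, 0.002))
            windows.append(w)
        out = oi.pi_stratified_fst(windows, "OWA", "p", n_perm=999, seed=1)
        tested = [r for r in out.values() if not isinstance(r, str)]
        assert tested and all(r.p_value < 0.05 for r in tested)


def ks_oracle(a, b):
    """Brute-force max ECDF gap over the pooled support."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    gaps = [abs((a <= x).mean() - (b <= x).mean())
            for x in np.concatenate([a, b])]
    return max(gaps)


class TestKs:
    def test_identical_samples(self):
        vals = list(range(10)) * 2
        labels = [True] * 10 + [False] * 10
        res = oi.ks_compare(vals, labels, n_tests=3)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_statistic_matches_ecdf_oracle_small_samples(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a = rng.normal(size=5)
            b = rng.normal(size=5)
            res = oi.ks_compare(np.concatenate([a, b]),
                                [True] * 5 + [False] * 5, n_tests=1)
            assert res.statistic == pytest.approx(ks_oracle(a, b), abs=1e-12)

    def test_shifted_distributions_reject_after_bonferroni(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, 200)
        b = rng.normal(3, 1, 200)
        res = oi.ks_compare(np.concatenate([a, b]),
                            [True] * 200 + [False] * 200, n_tests=3)
        assert res.p_bonferroni < 0.001
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p_value * 3))

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            oi.ks_compare([1.0, 2.0], [True, True])


class TestOverlaps:
    def test_enumerated_example(self):
        out = oi.overlap_counts({"A": {1, 2, 3}, "B": {2, 3}, "C": {3}})
        assert out[("A", "B")] == 2
        assert out[("A", "C")] == 1
        assert out[("B", "C")] == 1
        assert out[("A", "B", "C")] == 1

    def test_disjoint_sets(self):
        out = oi.overlap_counts({"A": {1}, "B": {2}, "C": {3}})
        assert all(v == 0 for v in out.values())

    def test_identical_sets(self):
        s = {1, 2, 3, 4}
        out = oi.overlap_counts({"A": set(s), "B": set(s), "C": set(s)})
        assert all(v == 4 for v in out.values())
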