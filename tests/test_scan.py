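from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan import scan
from sweepscan.matrix import MISSING
from sweepscan.simulate import SimulationConfig, simulate_cohort

from conftest import make_matrix


class TestMakeWindows:
    def test_enumerated_starts(self):
        windows = scan.make_windows({"s": 120_000})
        assert [(w.start, w.end) for w in windows] == [
            (0, 50_000),
            (25_000, 75_000),
            (50_000, 100_000),
            (75_000, 120_000),
            (100_000, 120_000),
        ]

    def test_length_equal_to_size(self):
        windows = scan.make_windows({"s": 50_000})
        assert [(w.start, w.end) for w in windows] == [(0, 50_000), (25_000, 50_000)]

    def test_short_scaffold_single_window(self):
        windows = scan.make_windows({"s": 10_000})
        assert [(w.start, w.end) for w in windows] == [(0, 10_000)]

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            scan.make_windows({"s": 0})

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError):
            scan.make_windows({"s": 100_000}, size=10_000, step=20_000)


def brute_force_hp(matrix, window):
    """Independent recount: pure-Python per-window Hp from raw genotypes."""
    s_maj = s_min = 0
    n_snps = 0
    for j in range(matrix.n_sites):
        site = matrix.sites.iloc[j]
        if site["scaffold"] != window.scaffold:
            continue
        if not (window.start <= site["pos"] - 1 < window.end):
            continue
        alt = ref = 0
        for i in range(matrix.n_samples):
            d = int(matrix.dosage[i, j])
            if d == MISSING:
                continue
            alt += d
            ref += 2 - d
        n_snps += 1
        s_maj += max(ref, alt)
        s_min += min(ref, alt)
    if n_snps < 2:
        return None
    total = s_maj + s_min
    return n_snps, float(Fraction(2 * s_maj * s_min, total * total))


class TestWindowHp:
    def test_printed_formula_hand_example(self):
        # per-site (nMAJ, nMIN) = (18,2), (15,5), (12,8): Hp = 2*45*15/60^2 = 0.375
        # 10 diploids = 20 alleles per site; dosages sum to the minor counts
        dosage = np.column_stack(
            [
                [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],  # 2 alt alleles
                [2, 2, 1, 0, 0, 0, 0, 0, 0, 0],  # 5
                [2, 2, 2, 1, 1, 0, 0, 0, 0, 0],  # 8
            ]
        ).astype(np.int8)
        matrix = make_matrix(dosage, spacing=100)
        stats = scan.window_hp(matrix, [scan.GenomicWindow("scaf1", 0, 50_000)])
        assert stats[0].sum_nmaj == 45
        assert stats[0].sum_nmin == 15
        assert stats[0].hp == pytest.approx(0.375, abs=1e-15)

    def test_balanced_counts_maximum(self):
        dosage = np.column_stack([[0, 2], [2, 0]]).astype(np.int8)
        stats = scan.window_hp(make_matrix(dosage), [scan.GenomicWindow("scaf1", 0, 50_000)])
        assert stats[0].hp == 0.5

    def test_monomorphic_window_zero(self):
        dosage = np.zeros((5, 3), dtype=np.int8)
        stats = scan.window_hp(make_matrix(dosage), [scan.GenomicWindow("scaf1", 0, 50_000)])
        assert stats[0].hp == 0.0

    def test_single_snp_window_discarded(self):
        dosage = np.ones((4, 1), dtype=np.int8)
        stats = scan.window_hp(make_matrix(dosage), [scan.GenomicWindow("scaf1", 0, 50_000)])
        assert stats == []

    def test_brute_force_equivalence(self):
        cfg = SimulationConfig(
            seed=55,
            scaffolds=[(f"s{i}", 120_000) for i in range(10)],
            populations=[("p", 12)],
            snp_density=1 / 2000,
            missing_rate=0.05,
        )
        cohort = simulate_cohort(cfg)
        windows = scan.make_windows(dict(cfg.scaffolds))
        stats = {s.window: s for s in scan.window_hp(cohort.matrix, windows)}
        for w in windows:
            expected = brute_force_hp(cohort.matrix, w)
            if expected is None:
                assert w not in stats
            else:
                assert stats[w].n_snps == expected[0]
                assert abs(stats[w].hp - expected[1]) < 1e-12

    def test_hp_bounds_and_tie_swap_invariance(self, small_cohort):
        windows = scan.make_windows(dict(small_cohort.config.scaffolds))
        for s in scan.window_hp(small_cohort.matrix, windows):
            assert 0.0 <= s.hp <= 0.5
            assert s.n_snps >= 2


class TestZTransform:
    def test_hand_example(self):
        z = scan.z_transform([0.1, 0.2, 0.3, 0.4, 0.5])
        # median 0.3, sample SD 0.15811
        assert z[0] == pytest.approx(-1.2649, abs=1e-4)

    def test_median_maps_to_zero(self):
        z = scan.z_transform([1.0, 2.0, 3.0])
        assert z[1] == 0.0

    def test_monotone(self, rng):
        values = rng.normal(size=50)
        z = scan.z_transform(values)
        assert np.array_equal(np.argsort(values), np.argsort(z))

    def test_degenerate_raises(self):
        with pytest.raises(scan.DegenerateDistributionError):
            scan.z_transform([1.0, 1.0, 1.0])


class TestEmpiricalThreshold:
    def test_interpolated_quantile(self):
        values = np.arange(1000, dtype=float)
        assert scan.empirical_threshold(values, 0.001, "lower") == pytest.approx(0.999)

    def test_constant_sample(self):
        assert scan.empirical_threshold([3.0] * 10, 0.01, "upper") == 3.0

    def test_declared_fraction_bounded(self, rng):
        for side in ("lower", "upper"):
            values = rng.normal(size=500)
            cutoff = scan.empirical_threshold(values, 0.01, side)
            frac = (
                np.mean(values <= cutoff) if side == "lower" else np.mean(values >= cutoff)
            )
            assert frac <= 0.01 + 1 / len(values) + 1e-12

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning):
            scan.empirical_threshold([1.0, 2.0, 3.0], 0.001, "lower")


def fst_components_rational(n1, p1, h1, n2, p2, h2):
    """Literal transcription of the variance components in exact arithmetic."""
    n1, n2 = Fraction(n1), Fraction(n2)
    p1, p2 = Fraction(p1), Fraction(p2)
    h1, h2 = Fraction(h1), Fraction(h2)
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (n_bar / n_c) * (
        s2 - Fraction(1, 1) / (n_bar - 1) * (p_bar * (1 - p_bar) - Fraction(r - 1, r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - Fraction(r - 1, r) * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


class TestFstComponents:
    def test_fixed_difference_theta_one(self):
        comp = scan.fst_site_components(10, 1.0, 0.0, 10, 0.0, 0.0)
        assert comp.theta == pytest.approx(1.0)

    def test_identical_populations_nonpositive_a(self):
        for p in (0.1, 0.3, 0.5, 0.7):
            h_max = 2 * min(p, 1 - p)  # feasible het fraction given p
            for frac in (0.0, 0.5, 1.0):
                comp = scan.fst_site_components(12, p, frac * h_max, 12, p, frac * h_max)
                assert comp.a <= 1e-12

    def test_matches_exact_rational_oracle(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(2, 40, size=2)
            # rational p/h so the oracle is exact
            p1 = Fraction(int(rng.integers(0, 2 * n1 + 1)), 2 * int(n1))
            p2 = Fraction(int(rng.integers(0, 2 * n2 + 1)), 2 * int(n2))
            h1 = Fraction(int(rng.integers(0, n1 + 1)), int(n1))
            h2 = Fraction(int(rng.integers(0, n2 + 1)), int(n2))
            if p1 == p2 and p1 in (0, 1) and h1 == h2 == 0:
                continue
            comp = scan.fst_site_components(
                int(n1), float(p1), float(h1), int(n2), float(p2), float(h2)
            )
            a, b, c = fst_components_rational(n1, p1, h1, n2, p2, h2)
            assert comp.a == pytest.approx(float(a), abs=1e-12)
            assert comp.b == pytest.approx(float(b), abs=1e-12)
            assert comp.c == pytest.approx(float(c), abs=1e-12)

    def test_monomorphic_site_zero_components(self):
        comp = scan.fst_site_components(10, 0.0, 0.0, 10, 0.0, 0.0)
        assert (comp.a, comp.b, comp.c) == (0.0, 0.0, 0.0)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            scan.fst_site_components(1, 0.5, 0.5, 10, 0.5, 0.5)


def two_pop_matrix(dos_a, dos_b):
    dosage = np.vstack([dos_a, dos_b])
    pops = ["a"] * len(dos_a) + ["b"] * len(dos_b)
    return make_matrix(dosage, populations=pops)


class TestWindowFst:
    def test_fixed_difference_window(self):
        dos_a = np.zeros((10, 10), dtype=np.int8)
        dos_b = np.full((10, 10), 2, dtype=np.int8)
        matrix = two_pop_matrix(dos_a, dos_b)
        stats = scan.window_fst(matrix, "a", "b", [scan.GenomicWindow("scaf1", 0, 50_000)])
        assert stats[0].fst_weighted == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        cfg = SimulationConfig(
            seed=91,
            scaffolds=[("s1", 1_000_000)],
            populations=[("a", 30), ("b", 30)],
            snp_density=1 / 1000,  # ~50 sites per 50-kb window
            F_divergence=0.0,
        )
        cohort = simulate_cohort(cfg)
        windows = scan.make_windows({"s1": 1_000_000})
        stats = scan.window_fst(cohort.matrix, "a", "b", windows)
        assert stats, "null scan produced no windows"
        assert max(s.fst_weighted for s in stats) <= 0.02

    def test_bn_divergence_recovered(self):
        for F in (0.05, 0.2):
            cfg = SimulationConfig(
                seed=92,
                scaffolds=[("s1", 2_000_000)],
                populations=[("a", 30), ("b", 30)],
                snp_density=1 / 1000,
                F_divergence=F,
            )
            cohort = simulate_cohort(cfg)
            fst = scan.genomewide_weighted_fst(cohort.matrix, "a", "b")
            assert abs(fst - F) < 0.05

    def test_single_snp_window_discarded(self):
        dos_a = np.array([[0, 0], [1, 1], [2, 0]], dtype=np.int8)
        dos_b = np.array([[2, 2], [1, 1], [0, 2]], dtype=np.int8)
        matrix = two_pop_matrix(dos_a, dos_b)
        # sites at 1000 and 2000: window covering only site 1 is discarded
        stats = scan.window_fst(matrix, "a", "b", [scan.GenomicWindow("scaf1", 0, 1500)])
        assert stats == []


class TestMergeSignificant:
    def _stat(self, scaffold, start, end, z):
        return scan.WindowStat(
            window=scan.GenomicWindow(scaffold, start, end), n_snps=2, hp=0.1, zhp=z
        )

    def test_interval_union(self):
        stats = [
            self._stat("s", 0, 50_000, -3.0),
            self._stat("s", 25_000, 75_000, -2.6),
            self._stat("s", 100_000, 150_000, -2.8),
        ]
        regions = scan.merge_significant(stats, mode="min")
        assert [(r.start, r.end) for r in regions] == [(0, 75_000), (100_000, 150_000)]
        assert regions[0].extreme == -3.0

    def test_abutting_windows_not_merged(self):
        stats = [self._stat("s", 0, 50_000, -3.0), self._stat("s", 50_000, 100_000, -2.6)]
        regions = scan.merge_significant(stats)
        assert len(regions) == 2

    def test_single_window_identity(self):
        stats = [self._stat("s", 0, 50_000, -3.0)]
        regions = scan.merge_significant(stats)
        assert (regions[0].start, regions[0].end) == (0, 50_000)
        assert regions[0].extreme == -3.0

    def test_cross_scaffold_never_merged(self):
        stats = [self._stat("s1", 0, 50_000, -3.0), self._stat("s2", 0, 50_000, -2.6)]
        assert len(scan.merge_significant(stats)) == 2

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.integers(1, 10)), min_size=1, max_size=15
        )
    )
    def test_regions_disjoint_and_sorted(self, raw):
        stats = [
            self._stat("s", start * 1000, (start + width) * 1000, -3.0)
            for start, width in raw
        ]
        regions = scan.merge_significant(stats)
        for r1, r2 in zip(regions, regions[1:]):
            assert r1.end <= r2.start
        assert sum(r.n_windows for r in regions) == len(stats)


class TestSweepRecoveryPower:
    def test_three_sweeps_found_at_wide_tail(self):
        sweeps = [
            ("s1", 1_000_000, 1_200_000),
            ("s1", 2_500_000, 2_700_000),
            ("s1", 4_000_000, 4_200_000),
        ]
        from sweepscan.simulate import SweepRegionSpec

        cfg = SimulationConfig(
            seed=5,
            scaffolds=[("s1", 5_000_000)],
            populations=[("pop", 30)],
            snp_density=1 / 500,
            sweep_regions=[SweepRegionSpec(s, a, b, "all", 0.98) for s, a, b in sweeps],
        )
        cohort = simulate_cohort(cfg)
        stats = scan.window_hp(cohort.matrix, scan.make_windows({"s1": 5_000_000}))
        scan.attach_zhp(stats)
        hits, _ = scan.significant_windows(stats, 0.05, side="lower")
        regions = scan.merge_significant(hits, mode="min")
        recovered = sum(
            any(r.start < e and s < r.end for r in regions) for _, s, e in sweeps
        )
        assert recovered >= 2
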