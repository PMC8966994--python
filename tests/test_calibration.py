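"""Accuracy/precision summaries, acquisition rate, and Kruskal-Wallis."""

import itertools
import math
from datetime import timedelta

import numpy as np
import pytest

from gpscal import (
    accuracy_summary,
    annotate_errors,
    fix_acquisition_rate,
    horizontal_precision,
    kruskal_wallis,
    kw_comparisons,
    summary_table,
    vertical_precision,
)
from gpscal.calibration import pairwise_distances
from gpscal.geodesy import geodesic_distance


class TestAccuracySummary:
    def test_hand_computed_horizontal(self, reference, make_fix):
        recs = annotate_errors(
            [make_fix(d, azimuth_deg=120.0 * i) for i, d in enumerate((3, 4, 5))],
            reference,
        )
        s = accuracy_summary(recs, "horizontal")
        assert s.n == 3
        assert s.mean == pytest.approx(4.0, abs=1e-6)
        assert s.sd == pytest.approx(1.0, abs=1e-6)  # sample (n-1) sd
        assert s.prop_below_10m == 1.0

    def test_vertical_symmetric_errors(self, reference, make_fix):
        recs = annotate_errors(
            [make_fix(0.0, alt_err=5.0), make_fix(0.0, alt_err=-5.0)], reference
        )
        s = accuracy_summary(recs, "vertical")
        # headline vertical accuracy is mean |error|; signed mean is the bias
        assert s.mean == pytest.approx(5.0)
        assert s.bias == pytest.approx(0.0)

    def test_all_fixes_at_reference(self, reference, make_fix):
        recs = annotate_errors([make_fix(0.0) for _ in range(4)], reference)
        s = accuracy_summary(recs, "horizontal")
        assert s.mean == pytest.approx(0.0, abs=1e-9)
        assert s.sd == pytest.approx(0.0, abs=1e-9)
        assert s.prop_below_10m == 1.0

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="grp"):
            accuracy_summary([], "horizontal", group="grp")


class TestPrecision:
    def test_identical_fixes(self, make_fix):
        fixes = [make_fix(0.0) for _ in range(3)]
        p = horizontal_precision(fixes)
        assert p.mean == pytest.approx(0.0, abs=1e-9)
        assert p.sd == pytest.approx(0.0, abs=1e-9)
        assert p.n_pairs == 3

    def test_collinear_fixes_hand_computed(self, make_fix):
        # three fixes 10 m apart on one geodesic: pair distances {10,10,20}
        fixes = [make_fix(d, azimuth_deg=90.0) for d in (0.0, 10.0, 20.0)]
        p = horizontal_precision(fixes)
        assert p.mean == pytest.approx(40.0 / 3.0, abs=1e-6)

    def test_matches_bruteforce_double_loop(self, make_fix):
        rng = np.random.default_rng(11)
        fixes = [
            make_fix(rng.uniform(0, 50), azimuth_deg=rng.uniform(0, 360),
                     alt_err=rng.normal(0, 5))
            for _ in range(50)
        ]
        p = horizontal_precision(fixes)
        brute = [
            geodesic_distance(a.lat, a.lon, b.lat, b.lon)
            for a, b in itertools.combinations(fixes, 2)
        ]
        assert p.n_pairs == len(brute) == 50 * 49 // 2
        assert p.mean == pytest.approx(np.mean(brute), abs=1e-9)
        assert p.sd == pytest.approx(np.std(brute, ddof=1), abs=1e-9)
        v = vertical_precision(fixes)
        brute_v = [abs(a.alt - b.alt) for a, b in itertools.combinations(fixes, 2)]
        assert v.mean == pytest.approx(np.mean(brute_v), abs=1e-12)

    def test_vertical_hand_computed(self, make_fix):
        fixes = [make_fix(0.0, alt_err=e) for e in (0.0, -2.0, -6.0)]
        # altitudes {ref, ref+2, ref+6}: |diffs| = {2, 6, 4}
        v = vertical_precision(fixes)
        assert v.mean == pytest.approx(4.0)

    def test_reorder_invariance(self, make_fix):
        rng = np.random.default_rng(5)
        fixes = [
            make_fix(rng.uniform(0, 30), azimuth_deg=rng.uniform(0, 360))
            for _ in range(20)
        ]
        a = horizontal_precision(fixes)
        b = horizontal_precision(list(reversed(fixes)))
        assert a.mean == pytest.approx(b.mean, abs=1e-9)

    def test_doubling_displacements_doubles_mean(self, make_fix):
        rng = np.random.default_rng(6)
        polar = [(rng.uniform(0, 30), rng.uniform(0, 360)) for _ in range(25)]
        f1 = [make_fix(d, azimuth_deg=a) for d, a in polar]
        f2 = [make_fix(2 * d, azimuth_deg=a) for d, a in polar]
        p1 = horizontal_precision(f1)
        p2 = horizontal_precision(f2)
        assert p2.mean == pytest.approx(2.0 * p1.mean, rel=1e-3)

    def test_subsampled_mean_close_to_exact(self, make_fix):
        rng = np.random.default_rng(7)
        fixes = [
            make_fix(rng.rayleigh(3.0), azimuth_deg=rng.uniform(0, 360))
            for _ in range(400)
        ]
        exact, sub_flag = pairwise_distances(fixes)
        assert not sub_flag
        sub, flag = pairwise_distances(fixes, max_pairs=20_000)
        assert flag
        assert sub.mean() == pytest.approx(exact.mean(), rel=0.05)

    def test_too_few_fixes_rejected(self, make_fix):
        with pytest.raises(ValueError):
            horizontal_precision([make_fix(0.0)])
        with pytest.raises(ValueError):
            vertical_precision([make_fix(0.0, alt_err=None), make_fix(1.0)])


class TestAcquisitionRate:
    def test_complete_and_partial(self):
        hour = timedelta(minutes=60)
        assert fix_acquisition_rate(timedelta(minutes=1), hour, 60) == 1.0
        assert fix_acquisition_rate(timedelta(minutes=1), hour, 45) == 0.75

    def test_over_unity_warns(self):
        with pytest.warns(UserWarning, match="> 1"):
            rate = fix_acquisition_rate(
                timedelta(minutes=1), timedelta(minutes=60), 66
            )
        assert rate == pytest.approx(1.1)

    def test_zero_expected_is_error(self):
        with pytest.raises(ValueError):
            fix_acquisition_rate(timedelta(hours=2), timedelta(hours=1), 0)

    def test_simulated_dropout_recovered(self):
        from gpscal import SimConfig, simulate_stationary

        cfg = SimConfig(dropout_prob=0.2, span_hours=100.0,
                        interval_minutes=1.0, seed=3)
        fixes, _ = simulate_stationary(cfg)
        rate = fix_acquisition_rate(
            timedelta(minutes=1), timedelta(hours=100), fixes
        )
        n = cfg.n_fixes_per_device
        ci = 3 * math.sqrt(0.8 * 0.2 / n)
        assert abs(rate - 0.8) < ci


def _exact_two_group_p(x, y):
    """Enumerate all group assignments; exact permutation p for KW H."""
    from scipy.stats import rankdata

    pooled = np.array(list(x) + list(y), dtype=float)
    n, n1 = pooled.size, len(x)
    ranks = rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = 1.0 - (counts**3 - counts).sum() / (n**3 - n)

    def h_for(idx):
        r1 = ranks[list(idx)]
        mask = np.ones(n, bool)
        mask[list(idx)] = False
        r2 = ranks[mask]
        h = (
            12.0 / (n * (n + 1))
            * (r1.sum() ** 2 / n1 + r2.sum() ** 2 / (n - n1))
            - 3.0 * (n + 1)
        )
        return h / tie_c

    h_obs = h_for(range(n1))
    hs = [h_for(c) for c in itertools.combinations(range(n), n1)]
    return np.mean([h >= h_obs - 1e-12 for h in hs])


class TestKruskalWallis:
    def test_hand_computed_no_ties(self):
        # ranks 1..6, rank sums 6 and 15 -> H = 27/7
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.H == pytest.approx(27.0 / 7.0, abs=1e-12)
        assert res.df == 1
        assert 0.0 < res.p < 0.06

    def test_identical_groups_with_ties(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]], p_method="permutation",
                             n_permutations=2000, seed=1)
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert res.p > 0.5

    def test_degenerate_all_identical(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.degenerate
        assert res.H == 0.0 and res.p == 1.0

    def test_three_groups_df(self):
        res = kruskal_wallis([[1, 5], [2, 6], [3, 9, 4]])
        assert res.df == 2
        assert res.group_sizes == (2, 2, 3)

    @pytest.mark.parametrize(
        "x,y",
        [([1.2, 3.4, 0.5, 2.2], [4.1, 5.0, 2.9, 6.3]),
         ([1, 1, 2, 3, 7], [2, 4, 4, 6, 8])],
    )
    def test_permutation_p_matches_exact_enumeration(self, x, y):
        exact = _exact_two_group_p(x, y)
        res = kruskal_wallis([x, y], p_method="permutation",
                             n_permutations=20_000, seed=2)
        mc_se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(res.p - exact) < 4 * mc_se + 1e-4

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestGroupedTables:
    def test_summary_table_has_device_and_pooled_rows(self, reference, make_fix):
        rng = np.random.default_rng(8)
        fixes = []
        for dev in ("dev01", "dev02"):
            for i in range(10):
                fixes.append(
                    make_fix(rng.rayleigh(3.0), azimuth_deg=rng.uniform(0, 360),
                             alt_err=rng.normal(0, 4), device=dev,
                             schedule="20min")
                )
        recs = annotate_errors(fixes, reference)
        df = summary_table(recs)
        devices = set(df["device"])
        assert devices == {"dev01", "dev02", "all"}
        assert set(df["axis"]) == {"horizontal", "vertical"}
        pooled = df[(df.device == "all") & (df.axis == "horizontal")]
        assert int(pooled["n"].iloc[0]) == 20

    def test_kw_comparisons_between_devices_and_schedules(self, reference, make_fix):
        rng = np.random.default_rng(9)
        fixes = []
        for sched, scale in (("1min", 2.0), ("60min", 6.0)):
            for dev in ("dev01", "dev02"):
                for i in range(15):
                    fixes.append(
                        make_fix(rng.rayleigh(scale), azimuth_deg=rng.uniform(0, 360),
                                 alt_err=rng.normal(0, scale), device=dev,
                                 schedule=sched)
                    )
        recs = annotate_errors(fixes, reference)
        df = kw_comparisons(recs)
        kinds = set(df["comparison"])
        assert kinds == {"between_devices", "between_schedules"}
        sched_row = df[(df.comparison == "between_schedules") & (df.axis == "horizontal")]
        assert int(sched_row["df"].iloc[0]) == 1
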