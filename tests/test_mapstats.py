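import numpy as np
import pandas as pd
import pytest

from rilmap import mapstats


class TestDistortion:
    def test_balanced_not_skewed(self):
        chi2, p = mapstats.chi2_1to1(32, 31)
        assert chi2 == pytest.approx(0.016, abs=1e-3)
        assert p == pytest.approx(0.90, abs=0.01)

    def test_skewed_example(self):
        chi2, p = mapstats.chi2_1to1(45, 18)
        assert chi2 == pytest.approx(11.57, abs=0.01)
        assert p == pytest.approx(6.7e-4, rel=0.05)
        assert p < 0.01

    def test_scan_merges_contiguous_regions(self):
        from rilmap.binmap import GeneticBin, GeneticMap
        rng = np.random.default_rng(1)
        lines = [f"R{i}" for i in range(60)]
        bins, rows = [], {}
        for k in range(6):
            skew = k in (2, 3)  # two contiguous distorted bins
            p_a = 0.9 if skew else 0.5
            calls = rng.choice(list("AB"), 60, p=[p_a, 1 - p_a])
            name = f"b{k}"
            rows[name] = calls
            enc = np.where(calls == "A", 0, 1).astype(np.int8)
            bins.append(GeneticBin(bin_id=name, members=[name],
                                   representative=name, calls=enc,
                                   cM=float(5 * k)))
        matrix = pd.DataFrame(rows, index=lines).T
        gmap = GeneticMap(groups={"LG1": bins}, lines=lines)
        records, regions = mapstats.distortion_scan(gmap, matrix, alpha=0.01)
        assert len(records) == 6
        flagged = [r.bin_id for r in records if r.p_value < 0.01]
        assert flagged == ["b2", "b3"]
        assert len(regions) == 1
        assert regions[0]["direction"] == "A"
        assert regions[0]["n_bins"] == 2


def _map_frame(order, lg="P1", spacing=1.0):
    return pd.DataFrame({
        "marker": order,
        "linkage_group": [lg] * len(order),
        "cM": [spacing * i for i in range(len(order))],
    })


class TestCollinearity:
    def test_identical_orders(self):
        a = _map_frame(list("abcdef"))
        _, summary = mapstats.collinearity(a, a.copy())
        assert summary["pooled_r_squared"] == pytest.approx(1.0)

    def test_reversed_order_also_perfect(self):
        a = _map_frame(list("abcdef"))
        b = _map_frame(list("fedcba"))
        results, _ = mapstats.collinearity(a, b)
        assert results[0].r_squared == pytest.approx(1.0)

    def test_partial_swap_worked_example(self):
        a = _map_frame(list("abcd"))
        b = _map_frame(["a", "c", "b", "d"])
        results, _ = mapstats.collinearity(a, b)
        assert results[0].r_squared == pytest.approx(0.64, abs=1e-9)

    def test_single_common_marker_undefined(self):
        a = _map_frame(["a"])
        b = _map_frame(["a"])
        results, _ = mapstats.collinearity(a, b)
        assert results[0].r_squared is None

    def test_other_lg_class_counted(self):
        a = _map_frame(list("abcd"), lg="P1")
        b = pd.concat([_map_frame(list("abc"), lg="P1"),
                       _map_frame(["d"], lg="P2")])
        _, summary = mapstats.collinearity(a, b)
        assert summary["n_other_lg"] == 1

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        order = [f"m{i}" for i in range(20)]
        a = _map_frame(order)
        b = _map_frame(list(rng.permutation(order)))
        _, s1 = mapstats.collinearity(a, b)
        a2 = a.copy()
        a2["cM"] = a2["cM"] * 3.7 + 11.0
        _, s2 = mapstats.collinearity(a2, b)
        assert s1["pooled_r_squared"] == pytest.approx(s2["pooled_r_squared"])

    def test_within_bin_ties_broken_by_other_map(self):
        a = pd.DataFrame({"marker": list("abcd"),
                          "linkage_group": ["P1"] * 4,
                          "cM": [0.0, 1.0, 1.0, 2.0]})  # b,c co-binned
        b = _map_frame(["a", "c", "b", "d"])
        results, _ = mapstats.collinearity(a, b)
        # tie in map A resolved by map B's order -> perfect collinearity
        assert results[0].r_squared == pytest.approx(1.0)


class TestCompareMaps:
    def test_identical_maps_zero_delta(self):
        a = _map_frame(list("abcde"))
        comp = mapstats.compare_maps(a, a.copy())
        assert comp["delta_total"] == 0.0
        assert all(row["delta"] == 0 for row in comp["per_lg"])

    def test_published_totals_worked_example(self):
        from rilmap import published
        res = published.length_difference(published.map_table("NM"),
                                          published.map_table("FA"))
        assert res["delta_cM"] == pytest.approx(19.0)
        assert res["delta_percent"] == pytest.approx(1.4, abs=0.05)

    def test_coverage_extension(self):
        # map B lacks map A's top marker: A extends 1 cM beyond the
        # outermost common markers, B does not
        a = _map_frame([f"m{i}" for i in range(10)], spacing=1.0)
        b = a[a["marker"] != "m0"].reset_index(drop=True)
        comp = mapstats.compare_maps(a, b)
        row = comp["per_lg"][0]
        assert row["extension_a"] == pytest.approx(1.0)
        assert row["extension_b"] == pytest.approx(0.0)


class TestRateProfile:
    def test_linear_map_constant_rate(self):
        mb = np.linspace(0, 100, 40)
        cm = 0.5 * mb
        prof = mapstats.rate_profile(cm, mb)
        interior = slice(20, 180)
        assert np.allclose(prof.rate[interior], 0.5, atol=0.02)

    def test_sigmoid_matches_analytic_derivative(self):
        L, s = 100.0, 16.0
        mb = np.linspace(0, L, 80)
        cm = 50.0 * (1 + np.tanh((mb - L / 2) / s))
        prof = mapstats.rate_profile(cm, mb)
        mid = np.argmin(np.abs(prof.grid_Mb - L / 2))
        analytic_peak = 50.0 / s  # d/dx 50(1+tanh((x-L/2)/s)) at x=L/2
        assert prof.rate[mid] == pytest.approx(analytic_peak, rel=0.05)
        assert prof.rate[3] < 0.1 * analytic_peak
        assert prof.rate[-4] < 0.1 * analytic_peak

    def test_integral_recovers_map_length(self):
        rng = np.random.default_rng(3)
        mb = np.sort(rng.uniform(0, 80, 60))
        cm = np.cumsum(rng.uniform(0, 1.5, 60))
        prof = mapstats.rate_profile(cm, mb)
        integral = np.trapezoid(prof.rate, prof.grid_Mb)
        span = prof.smoothed_cM[-1] - prof.smoothed_cM[0]
        assert integral == pytest.approx(span, rel=0.02)

    def test_duplicate_positions_averaged(self):
        mb = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        cm = np.array([0.0, 1.0, 3.0, 4.0, 5.0, 6.0])
        prof = mapstats.rate_profile(cm, mb)
        assert prof.grid_Mb[0] == 0.0

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ValueError):
            mapstats.rate_profile(np.arange(4), np.arange(4))

    def test_pericentromeric_suppression_recovered(self):
        from rilmap import simpop
        profile_fn = simpop.pericentromeric_profile(width=0.4,
                                                    suppression=0.02)
        genome = simpop.GenomeModel((100.0,), (100.0,), (profile_fn,))
        mb = np.linspace(0.5, 99.5, 80)
        cm = genome.physical_to_genetic(0, mb)
        prof = mapstats.rate_profile(cm, mb, bandwidth=3.0)
        centre = (prof.grid_Mb > 35) & (prof.grid_Mb < 65)
        assert prof.rate[centre].max() < 0.1


class TestNonrecombining:
    def test_uniform_rate_zero_fraction(self):
        prof = mapstats.RateProfile("c1", np.linspace(0, 10, 50),
                                    np.linspace(0, 10, 50),
                                    np.full(50, 1.0))
        assert mapstats.nonrecombining_fraction([prof], 0.01) == 0.0

    def test_half_zero_half_fraction(self):
        grid = np.linspace(0, 10, 101)
        rate = np.where(grid < 5, 0.0, 1.0)
        prof = mapstats.RateProfile("c1", grid, np.cumsum(rate) * 0.1, rate)
        frac = mapstats.nonrecombining_fraction([prof], 0.05)
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_printed_genome_values(self):
        from rilmap import published
        assert published.nonrecombining_percent() == pytest.approx(46.0,
                                                                   abs=0.1)
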