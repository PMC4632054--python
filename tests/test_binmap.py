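import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from rilmap import binmap, grouping, simpop
from conftest import make_matrix


def naive_count(X):
    """Reference COUNT: per line, transitions in the stripped sequence."""
    total = 0
    for col in X.T:
        seq = col[col >= 0]
        total += int((seq[1:] != seq[:-1]).sum())
    return total


class TestCountCrossovers:
    @given(arrays(np.int8, (8, 12), elements=st.integers(-1, 1)))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_naive(self, X):
        assert binmap.count_crossovers(X) == naive_count(X)

    def test_missing_interval_counts_once(self):
        X = np.array([[0], [-1], [-1], [1]], dtype=np.int8)
        assert binmap.count_crossovers(X) == 1


class TestBuildBins:
    def test_identical_markers_one_bin(self):
        m = make_matrix({"a": "AABB" * 10, "b": "AABB" * 10, "c": "AABB" * 10})
        bins = binmap.build_bins(m)
        assert len(bins) == 1
        assert sorted(bins[0].members) == ["a", "b", "c"]

    def test_representative_has_fewest_missing(self):
        base = "AABBAABB" * 5
        withmiss = base[:-2] + "--"
        m = make_matrix({"x": base, "y": withmiss})
        bins = binmap.build_bins(m)
        assert len(bins) == 1
        assert bins[0].representative == "x"

    def test_ambiguous_marker_attaches_to_more_shared_bin(self):
        # Z has zero recombination with both b1 and b2 (which recombine with
        # each other) through complementary missingness; Z shares more
        # informative lines with b1
        n = 60
        b1 = "A" * 30 + "B" * 30
        b2 = "A" * 40 + "B" * 20
        z = "A" * 30 + "-" * 10 + "B" * 10 + "-" * 10
        m = make_matrix({"b1": b1, "b2": b2, "z": z})
        bins = binmap.build_bins(m)
        by_member = {mm: b for b in bins for mm in b.members}
        assert len(bins) == 2
        assert by_member["z"] is by_member["b1"]
        assert "z" in by_member["z"].ambiguous

    def test_zero_recombination_invariant(self):
        rng = np.random.default_rng(5)
        rows = {f"m{i}": "".join(rng.choice(list("AB-"), 40,
                                            p=[0.42, 0.42, 0.16]))
                for i in range(12)}
        m = make_matrix(rows)
        rec = grouping.pairwise_recombination(m)
        bins = binmap.build_bins(m, rec)
        idx = {mk: i for i, mk in enumerate(rec.markers)}
        for b in bins:
            clean = [mm for mm in b.members if mm not in b.ambiguous]
            for i, x in enumerate(clean):
                for y in clean[i + 1:]:
                    xi, yi = idx[x], idx[y]
                    if rec.n_informative[xi, yi] >= 2:
                        assert rec.n_recombinant[xi, yi] == 0


class TestOrderBins:
    def test_two_bins_trivial(self):
        calls = np.array([[0, 0, 1], [0, 1, 1]], dtype=np.int8)
        order, cost = binmap.order_bins(calls)
        assert sorted(order) == [0, 1]

    def test_small_instances_match_exhaustive(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(3, 8))
            calls = rng.integers(0, 2, size=(n, 20)).astype(np.int8)
            calls[rng.random((n, 20)) < 0.1] = -1
            _, c_exh = binmap.exhaustive_order(calls)
            _, c_heu = binmap.order_bins(calls, seed=1, n_restarts=10)
            assert c_heu == c_exh

    def test_reflection_canonicalized(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 2, size=(6, 30)).astype(np.int8)
        ids = list("fedcba")
        order, _ = binmap.order_bins(calls, ids, seed=2)
        assert ids[order[0]] <= ids[order[-1]]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 2, size=(15, 40)).astype(np.int8)
        o1, c1 = binmap.order_bins(calls, seed=3)
        o2, c2 = binmap.order_bins(calls, seed=3)
        assert o1 == o2 and c1 == c2


class TestComputeDistances:
    def _ordered(self, pairs_r):
        """Build (n+1) bins whose adjacent observed R match given values."""
        n_lines = 200
        rng = np.random.default_rng(9)
        rows = [np.zeros(n_lines, dtype=np.int8)]
        for R in pairs_r:
            prev = rows[-1]
            flip = np.zeros(n_lines, dtype=bool)
            flip[: int(round(R * n_lines))] = True
            rng.shuffle(flip)
            rows.append(np.where(flip, 1 - prev, prev).astype(np.int8))
        return np.vstack(rows)

    def test_zero_r_zero_distance(self):
        X = self._ordered([0.0])
        pos = binmap.compute_distances(X)
        assert pos[1] == 0.0

    def test_haldane_worked_example(self):
        # adjacent observed R chosen so RIL-corrected r = 0.1
        R = float(grouping.ril_observed(0.1))
        X = self._ordered([R])
        pos = binmap.compute_distances(X)
        assert pos[1] == pytest.approx(-50 * np.log(0.8), abs=0.15)
        assert pos[1] == pytest.approx(11.157, abs=0.15)

    def test_kosambi_vs_haldane(self):
        R = float(grouping.ril_observed(0.2))
        X = self._ordered([R])
        h = binmap.compute_distances(X, "haldane")[1]
        k = binmap.compute_distances(X, "kosambi")[1]
        assert h == pytest.approx(25.541, abs=0.3)
        assert k == pytest.approx(21.182, abs=0.3)

    def test_unlinked_adjacency_capped_with_warning(self):
        X = self._ordered([0.5])
        with pytest.warns(UserWarning, match="capped"):
            pos = binmap.compute_distances(X)
        assert pos[1] == 50.0

    def test_masked_line_crossover_still_counted(self):
        # a line missing at the middle bin contributes its crossover
        # fractionally to both spanned intervals
        X = np.array([[0, 0], [0, -1], [0, 1]], dtype=np.int8)
        pos = binmap.compute_distances(X, min_informative=1)
        assert pos[2] > 0


class TestHetRegions:
    def _map_from(self, matrix, seed=0):
        groups = {"LG1": list(matrix.index)}
        return binmap.build_map(matrix, groups, seed=seed, max_gap_cM=None)

    def test_clean_line_no_regions(self):
        rng = np.random.default_rng(10)
        base = {}
        for i in range(30):
            base[f"m{i:02d}"] = "".join(
                rng.choice(list("AB"), 40))
        m = make_matrix(base)
        # marker m00..: make one clean line: single block pattern
        m.iloc[:, 0] = ["A"] * 15 + ["B"] * 15
        gmap = self._map_from(m)
        regs = binmap.detect_het_regions(gmap, m)
        assert not any(r.ril_id == m.columns[0] for r in regs)

    def test_constructed_noisy_tract_detected(self):
        # line R00 carries A...A [noisy missing/A/B tract] B...B on an
        # otherwise clean chromosome of block-structured lines
        rng = np.random.default_rng(11)
        lines = 80
        markers = 40
        tract = range(15, 25)
        cols = []
        for l in range(lines):
            if l == 0:
                col = ["A" if i < 15 else "B" for i in range(markers)]
                for i in tract:
                    col[i] = str(rng.choice(list("AB--")))
            else:
                xo = int(rng.integers(0, markers + 1))
                origin = int(rng.integers(2))
                col = ["AB"[origin] if i < xo else "AB"[1 - origin]
                       for i in range(markers)]
            cols.append(col)
        rows = {f"m{i:02d}": "".join(cols[l][i] for l in range(lines))
                for i in range(markers)}
        m = make_matrix(rows, rils=[f"R{l:02d}" for l in range(lines)])
        gmap = self._map_from(m, seed=1)
        regs = [r for r in binmap.detect_het_regions(gmap, m)
                if r.ril_id == "R00"]
        assert regs
        members = set().union(*(r.members for r in regs))
        hit = members & {f"m{i:02d}" for i in tract}
        assert len(hit) >= 5

    def test_regions_disjoint_per_line(self, small_calls):
        matrix, _, _ = small_calls
        groups = {"LG1": [m for m in matrix.index if m.startswith("UG01")]}
        gmap = binmap.build_map(matrix, groups, seed=2, max_gap_cM=None)
        regs = binmap.detect_het_regions(gmap, matrix)
        from collections import defaultdict
        by = defaultdict(list)
        for r in regs:
            by[(r.ril_id, r.linkage_group)].append((r.start_cM, r.end_cM))
        for spans in by.values():
            spans.sort()
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert a2 > b1


class TestBinConsensus:
    def test_majority_rule_worked_example(self):
        # 12 SPPs: 3 missing, 7 A, 2 B -> A (missing 25% < 80%, 7/9 >= 0.66)
        calls = pd.DataFrame({"R1": list("AAAAAAABB---")[:12]},
                             index=[f"s{i}" for i in range(12)]).T
        calls = calls.T.T  # keep shape (12 SPPs x 1 line)
        calls = pd.DataFrame({"R1": list("AAAAAAABB---")},
                             index=[f"s{i}" for i in range(12)])
        out = binmap.bin_consensus_alleles(calls, {f"s{i}": "b1"
                                                   for i in range(12)})
        assert out.at["b1", "R1"] == "A"

    def test_mostly_missing_is_missing(self):
        calls = pd.DataFrame({"R1": list("A" + "-" * 9)},
                             index=[f"s{i}" for i in range(10)])
        out = binmap.bin_consensus_alleles(calls, {f"s{i}": "b"
                                                   for i in range(10)})
        assert out.at["b", "R1"] == "-"

    def test_tie_is_missing(self):
        calls = pd.DataFrame({"R1": list("AAABBB")},
                             index=[f"s{i}" for i in range(6)])
        out = binmap.bin_consensus_alleles(calls, {f"s{i}": "b"
                                                   for i in range(6)})
        assert out.at["b", "R1"] == "-"

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        calls = pd.DataFrame(
            rng.choice(list("AB-"), size=(9, 8), p=[0.4, 0.4, 0.2]),
            index=[f"s{i}" for i in range(9)],
            columns=[f"R{i}" for i in range(8)])
        mapping = {f"s{i}": f"b{i % 3}" for i in range(9)}
        once = binmap.bin_consensus_alleles(calls, mapping)
        twice = binmap.bin_consensus_alleles(
            once, {b: b for b in once.index})
        pd.testing.assert_frame_equal(once.sort_index(), twice.sort_index())


class TestIterateMap:
    def test_clean_matrix_is_fixed_point(self):
        # no hets, no missing, and at most one crossover per line: every
        # correction step is a no-op and the final map equals iteration 1
        rng = np.random.default_rng(31)
        n_markers, n_lines = 25, 60
        cols = []
        for _ in range(n_lines):
            xo = int(rng.integers(0, n_markers + 1))
            origin = int(rng.integers(2))
            cols.append(["AB"[origin] if i < xo else "AB"[1 - origin]
                         for i in range(n_markers)])
        rows = {f"m{i:02d}": "".join(c[i] for c in cols)
                for i in range(n_markers)}
        clean = make_matrix(rows, rils=[f"R{l:02d}" for l in range(n_lines)])
        groups = {"LG1": list(clean.index)}
        res = binmap.iterate_map(clean, groups, seed=32, max_gap_cM=None)
        assert res.final.total_length == pytest.approx(
            res.iteration1.total_length)
        assert not res.het_regions

    def test_supported_double_crossover_survives(self):
        # line R0 carries a genuine double crossover at m05, backed by
        # unanimous multi-SPP support
        rng = np.random.default_rng(33)
        rows = {}
        for i in range(11):
            col = ["A" if (l + i) % 5 < 3 else "B" for l in range(40)]
            rows[f"m{i:02d}"] = "".join(col)
        m = make_matrix(rows, rils=[f"R{l:02d}" for l in range(40)])
        m.loc[:, "R00"] = "A"
        m.at["m05", "R00"] = "B"  # double crossover
        support = pd.DataFrame(7, index=m.index, columns=m.columns)
        res = binmap.iterate_map(m, {"LG1": list(m.index)}, seed=34,
                                 spp_support=support, max_gap_cM=None)
        assert res.corrected_matrix.at["m05", "R00"] == "B"

    def test_unsupported_double_crossover_removed(self):
        rng = np.random.default_rng(35)
        rows = {}
        for i in range(11):
            col = ["A" if (l + i) % 5 < 3 else "B" for l in range(40)]
            rows[f"m{i:02d}"] = "".join(col)
        m = make_matrix(rows, rils=[f"R{l:02d}" for l in range(40)])
        m.loc[:, "R00"] = "A"
        m.at["m05", "R00"] = "B"
        support = pd.DataFrame(7, index=m.index, columns=m.columns)
        support.at["m05", "R00"] = 1
        res = binmap.iterate_map(m, {"LG1": list(m.index)}, seed=36,
                                 spp_support=support, max_gap_cM=None)
        assert res.corrected_matrix.at["m05", "R00"] == "-"

    def test_reversal_invariance(self):
        genome = simpop.GenomeModel((70.0,))
        design = simpop.CrossDesign(n_rils=80, final_generation=8)
        truth_df, _ = simpop.simulate_population(
            genome, design, seed=37, markers_per_chrom=18)
        m = simpop.emit_call_matrix(truth_df, seed=38)
        groups = {"LG1": list(m.index)}
        map_f = binmap.build_map(m, groups, seed=39, max_gap_cM=None)
        map_r = binmap.build_map(m.iloc[::-1], groups, seed=39,
                                 max_gap_cM=None)
        seq_f = [b.bin_id for b in map_f.groups["LG1"]]
        seq_r = [b.bin_id for b in map_r.groups["LG1"]]
        assert seq_f == seq_r or seq_f == seq_r[::-1]

    def test_gap_splitting(self):
        a = {"m%02d" % i: "".join(
            "A" if (l + i) % 6 < 3 else "B" for l in range(50))
            for i in range(5)}
        rng = np.random.default_rng(40)
        b = {"n%02d" % i: "".join(rng.choice(list("AB"), 50))
             for i in range(5)}
        m = make_matrix({**a, **b}, rils=[f"R{l:02d}" for l in range(50)])
        gmap = binmap.build_map(m, {"LG1": list(m.index)}, seed=41,
                                max_gap_cM=30.0)
        assert len(gmap.groups) >= 2
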