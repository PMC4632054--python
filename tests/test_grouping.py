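import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rilmap import binmap, grouping, simpop
from conftest import make_matrix


class TestPairwiseRecombination:
    def test_identical_columns(self):
        m = make_matrix({"a": "AABB" * 15, "b": "AABB" * 15})
        rec = grouping.pairwise_recombination(m)
        assert rec.n_informative[0, 1] == 60
        assert rec.R_hat[0, 1] == 0.0
        assert rec.r_hat[0, 1] == 0.0

    def test_worked_example_ten_of_sixty(self):
        a = "A" * 60
        b = "B" * 10 + "A" * 50
        rec = grouping.pairwise_recombination(make_matrix({"a": a, "b": b}))
        assert rec.R_hat[0, 1] == pytest.approx(1 / 6)
        assert rec.r_hat[0, 1] == pytest.approx(0.100)

    def test_complementary_columns_clamped_repulsion(self):
        a = "AB" * 20
        b = "BA" * 20
        rec = grouping.pairwise_recombination(make_matrix({"a": a, "b": b}))
        assert rec.R_hat[0, 1] == 1.0
        assert rec.r_hat[0, 1] == 0.5
        assert rec.lod[0, 1] <= 0

    def test_h_treated_as_missing(self):
        m = make_matrix({"a": "AHBB", "b": "AABB"})
        rec = grouping.pairwise_recombination(m)
        assert rec.n_informative[0, 1] == 3

    def test_all_missing_marker_excluded(self):
        m = make_matrix({"a": "AABB", "b": "----"})
        with pytest.warns(UserWarning, match="excluded"):
            rec = grouping.pairwise_recombination(m)
        assert rec.markers == ["a"]

    @given(st.floats(0.0, 0.49))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ril_correction_round_trip(self, r):
        R = grouping.ril_observed(r)
        assert grouping.ril_correction(R) == pytest.approx(r, abs=1e-12)

    def test_finite_generation_limits(self):
        # F2 closed form: R = r^2 / ((1-r)^2 + r^2); F_inf: 2r/(1+2r)
        r = 0.1
        f2 = grouping.ril_observed_finite(r, 2)
        assert f2 == pytest.approx(r ** 2 / ((1 - r) ** 2 + r ** 2), abs=1e-12)
        f30 = grouping.ril_observed_finite(r, 30)
        assert f30 == pytest.approx(float(grouping.ril_observed(r)), abs=1e-4)

    def test_finite_correction_round_trip(self):
        for r in (0.02, 0.1, 0.3):
            R = grouping.ril_observed_finite(r, 7)
            assert grouping.ril_correction_finite(R, 7) == pytest.approx(
                r, abs=2e-3)


class TestClustering:
    def _two_blocks(self):
        rng = np.random.default_rng(1)
        a = rng.choice(list("AB"), 60)
        b = rng.choice(list("AB"), 60)
        rows = {}
        for i in range(4):
            v = a.copy()
            flip = rng.random(60) < 0.02
            v[flip] = np.where(v[flip] == "A", "B", "A")
            rows[f"x{i}"] = "".join(v)
        for i in range(4):
            v = b.copy()
            flip = rng.random(60) < 0.02
            v[flip] = np.where(v[flip] == "A", "B", "A")
            rows[f"y{i}"] = "".join(v)
        return make_matrix(rows)

    def test_two_blocks_two_clusters(self):
        rec = grouping.pairwise_recombination(self._two_blocks())
        lgs = grouping.cluster_linkage_groups(rec)
        assert lgs.n_groups == 2
        members = sorted(tuple(sorted(c)) for c in lgs.clusters)
        assert members == [("x0", "x1", "x2", "x3"), ("y0", "y1", "y2", "y3")]

    def test_transitive_chain_one_cluster(self):
        rng = np.random.default_rng(2)
        a = rng.choice(list("AB"), 80)

        def drift(v, k):
            v = v.copy()
            flip = rng.choice(80, k, replace=False)
            v[flip] = np.where(v[flip] == "A", "B", "A")
            return v

        b = drift(a, 12)
        c = drift(b, 12)
        m = make_matrix({"a": "".join(a), "b": "".join(b), "c": "".join(c)})
        rec = grouping.pairwise_recombination(m)
        lgs = grouping.cluster_linkage_groups(rec)
        assert lgs.n_groups == 1

    def test_permutation_invariance(self):
        m = self._two_blocks()
        rec1 = grouping.pairwise_recombination(m)
        rec2 = grouping.pairwise_recombination(m.iloc[::-1])
        c1 = grouping.cluster_linkage_groups(rec1)
        c2 = grouping.cluster_linkage_groups(rec2)
        assert [sorted(c) for c in c1.clusters] == \
            [sorted(c) for c in c2.clusters]

    def test_matches_bruteforce_components(self):
        rng = np.random.default_rng(3)
        rows = {f"m{i}": "".join(rng.choice(list("AB-"), 40,
                                            p=[0.45, 0.45, 0.1]))
                for i in range(8)}
        m = make_matrix(rows)
        rec = grouping.pairwise_recombination(m)
        lgs = grouping.cluster_linkage_groups(rec, max_r=0.3, min_lod=2.0)
        # brute force: connected components of the thresholded pair graph
        idx = {mk: i for i, mk in enumerate(rec.markers)}
        comp = {mk: {mk} for mk in rec.markers}
        changed = True
        while changed:
            changed = False
            for a, b in itertools.combinations(rec.markers, 2):
                i, j = idx[a], idx[b]
                good = (np.isfinite(rec.r_hat[i, j])
                        and rec.r_hat[i, j] <= 0.3 and rec.lod[i, j] >= 2.0)
                if good and comp[a] is not comp[b]:
                    merged = comp[a] | comp[b]
                    for mk in merged:
                        comp[mk] = merged
                    changed = True
        want = sorted({tuple(sorted(s)) for s in comp.values()})
        got = sorted(tuple(sorted(c))
                     for c in lgs.clusters + [[s] for s in lgs.singletons])
        assert got == want

    def test_twelve_chromosomes_yield_twelve_clusters(self):
        genome = simpop.GenomeModel(tuple([110.0] * 12))
        design = simpop.CrossDesign(n_rils=120, final_generation=8)
        truth_df, _ = simpop.simulate_population(
            genome, design, seed=11, markers_per_chrom=40)
        m = simpop.emit_call_matrix(truth_df, seed=12)
        rec = grouping.pairwise_recombination(m)
        lgs = grouping.cluster_linkage_groups(rec)
        assert lgs.n_groups == 12


class TestPseudolinkage:
    def test_constructed_concatenation_splits(self):
        # two independent chromosomes whose clusters are joined only through
        # a localized linking block
        genome = simpop.GenomeModel((60.0, 60.0))
        design = simpop.CrossDesign(n_rils=150, final_generation=8,
                                    translocation=(0, 1, 30.0, 30.0))
        truth_df, truth = simpop.simulate_population(
            genome, design, seed=21, markers_per_chrom=25)
        m = simpop.emit_call_matrix(truth_df, seed=22)
        rec = grouping.pairwise_recombination(m)
        lgs = grouping.cluster_linkage_groups(rec)
        merged = max(lgs.clusters, key=len)
        assert len(merged) >= 45  # pseudolinkage fused the chromosomes
        sub = m.loc[merged]
        bins = binmap.build_bins(sub, grouping.pairwise_recombination(sub))
        reps = [b.representative for b in bins]
        res = grouping.detect_pseudolinkage(
            grouping.pairwise_recombination(m.loc[reps]), reps)
        assert res.split
        assert res.breakpoint_bin is not None
        bp_cm = truth.marker_cM[res.breakpoint_bin]
        assert abs(bp_cm - 30.0) < 8.0

    def test_negative_control_no_flags(self):
        genome = simpop.GenomeModel((120.0,))
        design = simpop.CrossDesign(n_rils=120, final_generation=8)
        truth_df, _ = simpop.simulate_population(
            genome, design, seed=23, markers_per_chrom=48)
        m = simpop.emit_call_matrix(truth_df, seed=24)
        bins = binmap.build_bins(m, grouping.pairwise_recombination(m))
        reps = [b.representative for b in bins]
        res = grouping.detect_pseudolinkage(
            grouping.pairwise_recombination(m.loc[reps]), reps)
        assert not res.split
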