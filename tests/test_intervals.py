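"""Interval arithmetic, consensus peaks, and the hypergeometric test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crescape.intervals import (
    OverlapEnrichmentQuery,
    consensus_peaks,
    filter_fragments,
    hypergeom_upper,
    intersect_any,
    nearest_tss,
    reciprocal_overlap_scores,
    shared_across,
    within_window,
)
from conftest import brute_force_overlaps, random_intervals


def df(rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


class TestIntersectAny:
    def test_one_bp_overlap_counts(self):
        a = df([("chr1", 100, 200)])
        b = df([("chr1", 199, 300)])
        assert len(intersect_any(a, b)) == 1

    def test_half_open_abutment_never_overlaps(self):
        a = df([("chr1", 100, 200)])
        b = df([("chr1", 200, 300)])
        assert len(intersect_any(a, b)) == 0

    def test_each_row_returned_once(self):
        a = df([("chr1", 100, 200)])
        b = df([("chr1", 110, 120), ("chr1", 150, 160)])
        assert len(intersect_any(a, b)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, 200)
        b = random_intervals(rng, 200)
        got = sorted(intersect_any(a, b).index)
        assert got == brute_force_overlaps(a, b)


class TestSharedAcross:
    def test_sharing_degrees(self):
        s1 = df([("chr1", 0, 100), ("chr1", 1000, 1100)])
        s2 = df([("chr1", 50, 150)])
        s3 = df([("chr1", 80, 90)])
        out = shared_across([s1, s2, s3])
        assert out[0]["fully_shared"].tolist() == [True, False]
        assert out[0]["specific"].tolist() == [False, True]

    def test_partial_share_is_neither(self):
        s1 = df([("chr1", 0, 100)])
        s2 = df([("chr1", 50, 150)])
        s3 = df([("chr1", 500, 600)])
        out = shared_across([s1, s2, s3])
        assert not out[0]["fully_shared"].iat[0]
        assert not out[0]["specific"].iat[0]

    def test_disjoint_sets_all_specific(self):
        s1 = df([("chr1", 0, 10)])
        s2 = df([("chr1", 100, 110)])
        out = shared_across([s1, s2])
        assert out[0]["specific"].all() and out[1]["specific"].all()


class TestNearestTss:
    def test_containment_distance_zero(self):
        feats = df([("chr1", 500, 700)])
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [600]})
        out = nearest_tss(feats, tss)
        assert out["tss_dist"].iat[0] == 0
        assert out["tss_class"].iat[0] == "proximal"

    def test_distance_2000_is_distal(self):
        feats = df([("chr1", 0, 100)])
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [2099]})
        out = nearest_tss(feats, tss)
        assert out["tss_dist"].iat[0] == 2000
        assert out["tss_class"].iat[0] == "distal"

    def test_empty_tss_table_errors(self):
        with pytest.raises(ValueError):
            nearest_tss(df([("chr1", 0, 10)]), pd.DataFrame(columns=["chrom", "pos"]))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        feats = random_intervals(rng, 100)
        tss = pd.DataFrame({"chrom": "chr1",
                            "pos": rng.integers(0, 100_000, size=30)})
        out = nearest_tss(feats, tss)
        for i, r in feats.iterrows():
            dists = []
            for t in tss["pos"]:
                if r["start"] <= t < r["end"]:
                    dists.append(0)
                elif t < r["start"]:
                    dists.append(r["start"] - t)
                else:
                    dists.append(t - (r["end"] - 1))
            assert out.loc[i, "tss_dist"] == min(dists)


class TestWithinWindow:
    def test_inside_window_pairs(self):
        feats = df([("chr1", 1_000, 1_200)])
        genes = df([("chr1", 100_000, 105_000)])
        assert len(within_window(feats, genes, 100_000)) == 1

    def test_outside_window_not_paired(self):
        feats = df([("chr1", 0, 100)])
        genes = df([("chr1", 100_200, 105_000)])
        assert len(within_window(feats, genes, 100_000)) == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        feats = random_intervals(rng, 80, max_pos=500_000)
        genes = random_intervals(rng, 30, max_pos=500_000, max_len=5000)
        w = 50_000
        pairs = within_window(feats, genes, w)
        got = {(f, g) for f, g in zip(pairs["feature_index"],
                                      pairs["gene_index"])}
        expected = set()
        for fi, rf in feats.iterrows():
            for gi, rg in genes.iterrows():
                if rf["start"] < rg["end"] + w and rf["end"] > rg["start"] - w:
                    expected.add((fi, gi))
        assert got == expected


class TestConsensusPeaks:
    def test_two_of_three_kept(self):
        r1 = df([("chr1", 100, 200)])
        r2 = df([("chr1", 150, 250)])
        r3 = df([("chr1", 5000, 5100)])
        cons = consensus_peaks([r1, r2, r3], 0.66)
        assert len(cons) == 1  # ceil(0.66*3)=2 replicates required
        assert cons.iloc[0]["start"] == 100 and cons.iloc[0]["end"] == 250

    def test_single_replicate_support_dropped(self):
        r1 = df([("chr1", 100, 200)])
        r2 = df([("chr1", 5000, 5100)])
        r3 = df([("chr1", 9000, 9100)])
        assert len(consensus_peaks([r1, r2, r3], 0.66)) == 0

    def test_two_of_two_kept(self):
        r1 = df([("chr1", 100, 200)])
        r2 = df([("chr1", 150, 250)])
        assert len(consensus_peaks([r1, r2], 0.66)) == 1

    def test_lower_fraction_never_shrinks_output(self):
        rng = np.random.default_rng(3)
        reps = [random_intervals(rng, 50, max_pos=20_000) for _ in range(4)]
        strict = consensus_peaks(reps, 0.9)
        loose = consensus_peaks(reps, 0.4)
        assert len(loose) >= len(strict)


class TestFilterFragments:
    def test_boundary_is_strict(self):
        frags = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 0],
                              "end": [99, 100], "length": [99, 100]})
        kept = filter_fragments(frags, 100)
        assert kept["length"].tolist() == [99]

    def test_negative_length_errors(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                              "length": [-5]})
        with pytest.raises(ValueError):
            filter_fragments(frags)

    def test_empty_input(self):
        frags = pd.DataFrame(columns=["chrom", "start", "end", "length"])
        assert len(filter_fragments(frags)) == 0


def enumeration_upper_tail(N, K, n, k):
    """Exhaustive oracle: enumerate every n-subset of an N-universe."""
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


class TestHypergeomUpper:
    def test_worked_example(self):
        p = hypergeom_upper(OverlapEnrichmentQuery(k=2, n=3, K=4, N=10))
        assert math.isclose(p, 40 / 120, rel_tol=0, abs_tol=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_upper(OverlapEnrichmentQuery(k=0, n=3, K=4, N=10)) == 1.0

    def test_forced_maximum_is_one(self):
        assert hypergeom_upper(OverlapEnrichmentQuery(k=5, n=5, K=5, N=5)) == 1.0

    def test_invalid_arguments_error(self):
        with pytest.raises(ValueError):
            OverlapEnrichmentQuery(k=5, n=3, K=4, N=10)
        with pytest.raises(ValueError):
            OverlapEnrichmentQuery(k=1, n=3, K=11, N=10)

    def test_matches_enumeration_small_universes(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        p = hypergeom_upper(
                            OverlapEnrichmentQuery(k=k, n=n, K=K, N=N))
                        assert abs(p - enumeration_upper_tail(N, K, n, k)) < 1e-12

    def test_monotone_nonincreasing_in_k(self):
        vals = [hypergeom_upper(OverlapEnrichmentQuery(k=k, n=20, K=30, N=100))
                for k in range(21)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))


class TestReciprocalOverlapScores:
    def test_perfect_recovery(self):
        truth = df([("chr1", 0, 100), ("chr1", 500, 600)])
        out = reciprocal_overlap_scores(truth.copy(), truth)
        assert out["recall"] == 1.0 and out["precision"] == 1.0

    def test_small_fragment_fails_match(self):
        truth = df([("chr1", 0, 1000)])
        called = df([("chr1", 0, 100)])
        out = reciprocal_overlap_scores(called, truth)
        assert out["recall"] == 0.0 and out["precision"] == 0.0
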