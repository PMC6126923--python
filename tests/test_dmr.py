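"""Differential-hypomethylation calling: site test, chaining, merging."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from crescape.dmr import (
    DmrParams,
    assign_ects_hypo_dmrs,
    call_dmrs,
    merge_large_hypo_dmrs,
    require_replicate_support,
    rms_site_test,
    rms_statistic,
)
from crescape.methylome import MethylomeTrack
from crescape.simulate import dmr_study


def track_from(pos, mc, cov, sample="s", rep="1"):
    return MethylomeTrack(pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "mc": mc, "cov": cov}),
        sample=sample, replicate=rep)


class TestRmsSiteTest:
    def test_perfect_homogeneity(self):
        p, signs = rms_site_test([5, 5], [10, 10], num_sims=500, seed=0)
        assert p == 1.0
        assert rms_statistic(np.array([5.0, 5.0]), np.array([10.0, 10.0])) == 0

    def test_extreme_difference_bounded_by_fisher(self):
        # Fisher's exact on the 2x2 table is the small-table oracle:
        # (10/10 vs 0/10) gives p = 1.08e-5, so the Monte-Carlo estimate
        # must be far below the 0.01 working cutoff
        _, fisher_p = fisher_exact([[10, 0], [0, 10]])
        assert fisher_p < 1e-4
        p, signs = rms_site_test([10, 0], [10, 10], num_sims=3000, seed=0)
        assert p <= 0.01
        assert signs[0] > 0 and signs[1] < 0

    def test_single_covered_sample_skipped(self):
        with pytest.raises(ValueError):
            rms_statistic(np.array([1.0, 0.0]), np.array([10.0, 0.0]))
        with pytest.warns(UserWarning):
            p, _ = rms_site_test([1, 0], [10, 0], num_sims=500, seed=0)
        assert np.isnan(p)

    def test_screened_and_exact_paths_agree_on_calls(self):
        from crescape.dmr import rms_site_tests

        rng = np.random.default_rng(0)
        cov = rng.poisson(15, size=(300, 2)).clip(1)
        mc = rng.binomial(cov, 0.5)
        p_screen, _ = rms_site_tests(mc, cov, 2000, seed=1)
        p_exact, _ = rms_site_tests(mc, cov, 2000, seed=1, screen_alpha=None)
        sig_s = p_screen < 0.01
        sig_e = p_exact < 0.01
        assert (sig_s == sig_e).mean() > 0.99


class TestCallDmrs:
    def two_sample_tracks(self, positions):
        """Strong hypo signal in sample A at every given position."""
        n = len(positions)
        a = track_from(positions, [0] * n, [20] * n, "A")
        b = track_from(positions, [20] * n, [20] * n, "B")
        return {"A": a, "B": b}

    def test_sites_within_max_dist_chain_into_one_dmr(self):
        pos = [0, 200, 400, 600]
        dmrs = call_dmrs(self.two_sample_tracks(pos), seed=0)
        assert len(dmrs) == 1
        assert dmrs["hypo_samples"].iat[0] == "A"
        assert dmrs["n_sites"].iat[0] == 4

    def test_sites_beyond_max_dist_split(self):
        params = DmrParams(min_dms=4)
        pos = [0, 100, 200, 249, 549, 649, 749, 799]  # gap 300 in middle
        dmrs = call_dmrs(self.two_sample_tracks(pos), params, seed=0)
        assert len(dmrs) == 2

    def test_chains_shorter_than_min_dms_dropped(self):
        pos = [0, 200, 400]
        dmrs = call_dmrs(self.two_sample_tracks(pos),
                         DmrParams(min_dms=4), seed=0)
        assert len(dmrs) == 0

    def test_reported_dmrs_satisfy_min_diff(self):
        study = dmr_study(seed=4, n_blocks=10, chrom_length=400_000)
        dmrs = call_dmrs(study["pooled"], seed=0)
        assert len(dmrs) > 0
        gap = dmrs["mean_B"] - dmrs["mean_A"]
        assert (gap >= DmrParams().min_diff).all()


class TestReplicateSupport:
    def make_dmr_row(self):
        return pd.DataFrame([{
            "chrom": "chr1", "start": 0, "end": 100, "n_sites": 4,
            "hypo_samples": "A", "p_summary": 1e-4,
            "mean_A": 0.06, "mean_B": 0.7,
        }])

    def replicates(self, rep_fracs):
        pos = [10, 30, 50, 70]
        reps = []
        for f in rep_fracs:
            mc = int(round(f * 20))
            reps.append(track_from(pos, [mc] * 4, [20] * 4, "A"))
        b = [track_from(pos, [14] * 4, [20] * 4, "B")]
        return {"A": reps, "B": b}

    def test_both_replicates_low_retained(self):
        out = require_replicate_support(self.make_dmr_row(),
                                        self.replicates([0.05, 0.08]))
        assert len(out) == 1

    def test_one_discordant_replicate_drops_dmr(self):
        out = require_replicate_support(self.make_dmr_row(),
                                        self.replicates([0.05, 0.55]))
        assert len(out) == 0

    def test_single_replicate_retained_with_warning(self):
        with pytest.warns(UserWarning, match="one replicate"):
            out = require_replicate_support(self.make_dmr_row(),
                                            self.replicates([0.05]))
        assert len(out) == 1


class TestEctsAssignment:
    def test_unique_vs_shared_hypo_sets(self):
        dmrs = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 100,
             "hypo_samples": "brain"},
            {"chrom": "chr1", "start": 500, "end": 600,
             "hypo_samples": "brain,lung"},
        ])
        all_hypo, ects = assign_ects_hypo_dmrs(
            dmrs, ["brain", "liver", "lung", "kidney"])
        assert len(ects["brain"]) == 1
        assert len(ects["lung"]) == 0
        assert len(all_hypo["brain"]) == 2
        assert len(all_hypo["lung"]) == 1
        assert len(all_hypo["liver"]) == 0


def brute_force_merge(intervals, gap, min_len):
    """O(n^2) merge oracle: repeatedly union any pair within gap."""
    ivs = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                a, b = ivs[i], ivs[j]
                if a is None or b is None:
                    continue
                lo, hi = (a, b) if a[0] <= b[0] else (b, a)
                if hi[0] - lo[1] <= gap:
                    ivs[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    ivs[j] = None
                    changed = True
        ivs = [iv for iv in ivs if iv is not None]
    return sorted([iv for iv in ivs if iv[1] - iv[0] > min_len])


class TestMergeLargeHypoDmrs:
    def as_df(self, intervals):
        return pd.DataFrame([{"chrom": "chr1", "start": s, "end": e}
                             for s, e in intervals])

    def test_worked_example(self):
        merged = merge_large_hypo_dmrs(
            self.as_df([(0, 100), (900, 1300), (3000, 5200)]))
        assert merged[["start", "end"]].values.tolist() == [[3000, 5200]]

    def test_gap_exactly_1000_merges(self):
        merged = merge_large_hypo_dmrs(self.as_df([(0, 600), (1600, 3200)]))
        assert merged[["start", "end"]].values.tolist() == [[0, 3200]]

    def test_length_exactly_2000_dropped(self):
        assert len(merge_large_hypo_dmrs(self.as_df([(0, 2000)]))) == 0

    def test_empty_input(self):
        assert len(merge_large_hypo_dmrs(self.as_df([]))) == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        starts = rng.integers(0, 50_000, size=n)
        ivs = sorted((int(s), int(s + rng.integers(50, 3000)))
                     for s in starts)
        got = merge_large_hypo_dmrs(self.as_df(ivs))
        expected = brute_force_merge(ivs, 1000, 2000)
        assert got[["start", "end"]].values.tolist() == \
            [list(iv) for iv in expected]


class TestNullAndPower:
    def test_null_pair_type_i_control(self):
        study = dmr_study(seed=11, n_blocks=0, chrom_length=250_000)
        from crescape.dmr import align_tracks, rms_site_tests

        aligned = align_tracks(study["pooled"])
        mc = aligned[["mc_A", "mc_B"]].to_numpy(float)
        cov = aligned[["cov_A", "cov_B"]].to_numpy(float)
        p, _ = rms_site_tests(mc, cov, 3000, seed=0)
        frac = np.mean(p[~np.isnan(p)] < 0.01)
        assert frac <= 0.02
        dmrs = call_dmrs(study["pooled"], seed=0)
        assert len(dmrs) <= max(1, 5 * len(aligned) // 100_000)

    def test_planted_blocks_recovered(self):
        from crescape.intervals import reciprocal_overlap_scores

        study = dmr_study(seed=12, n_blocks=15, chrom_length=500_000,
                          delta=0.4)
        dmrs = call_dmrs(study["pooled"], seed=0)
        dmrs = require_replicate_support(dmrs, study["replicate_tracks"])
        sc = reciprocal_overlap_scores(dmrs, study["truth"])
        assert sc["recall"] >= 0.9
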