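"""PWM scanning, enrichment, GC-matched backgrounds, spacing analysis."""

import numpy as np
import pandas as pd
import pytest

from crescape.motifs import (
    Pwm,
    best_hits,
    build_paired_model,
    center_on_anchor,
    count_instances,
    detect_spike,
    edge_gap,
    gc_fraction,
    kmer_enrichment,
    motif_enrichment,
    revcomp,
    sample_gc_matched_background,
    scan,
    spacing_histogram,
    spike_offset_for_gap,
)
from crescape.simulate import (
    ETS_CONSENSUS,
    ZIC_CONSENSUS,
    GenomeSpec,
    MotifEmbeddingSpec,
    embed_motif_pairs,
    generate_genome,
)


def random_regions(rng, n, length=300, gc=0.42):
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {f"r{i}": "".join(bases[rng.choice(4, size=length, p=p)])
            for i in range(n)}


class TestScan:
    def test_embedded_consensus_found_with_max_score(self, ets_pwm):
        rng = np.random.default_rng(0)
        seq = random_regions(rng, 1, length=100)["r0"]
        seq = seq[:37] + ets_pwm.consensus + seq[37 + len(ets_pwm):]
        hits = scan({"x": seq}, ets_pwm)
        top = hits.sort_values("score", ascending=False).iloc[0]
        assert top["start"] == 37 and top["strand"] == "+"
        assert top["score"] == pytest.approx(ets_pwm.max_score)

    def test_reverse_complement_hits_mirrored_minus_strand(self, ets_pwm):
        rng = np.random.default_rng(1)
        seq = random_regions(rng, 1, length=100)["r0"]
        seq = seq[:20] + revcomp(ets_pwm.consensus) + seq[20 + len(ets_pwm):]
        hits = scan({"x": seq}, ets_pwm)
        top = hits.sort_values("score", ascending=False).iloc[0]
        assert top["start"] == 20 and top["strand"] == "-"

    def test_threshold_above_max_gives_no_hits(self, ets_pwm):
        hits = scan({"x": ets_pwm.consensus * 3}, ets_pwm,
                    threshold=ets_pwm.max_score + 1)
        assert len(hits) == 0

    def test_strand_symmetry_property(self, ets_pwm):
        rng = np.random.default_rng(2)
        seqs = random_regions(rng, 10, length=200)
        fwd = scan(seqs, ets_pwm, threshold=0.5 * ets_pwm.max_score)
        rc = scan({k: revcomp(v) for k, v in seqs.items()}, ets_pwm,
                  threshold=0.5 * ets_pwm.max_score)
        L = 200 - len(ets_pwm)
        mapped = {(r, L - s, {"+": "-", "-": "+"}[st])
                  for r, s, st in zip(rc["region"], rc["start"], rc["strand"])}
        orig = set(zip(fwd["region"], fwd["start"], fwd["strand"]))
        assert mapped == orig

    def test_region_shorter_than_pwm_skipped(self, ets_pwm):
        assert len(scan({"tiny": "ACG"}, ets_pwm)) == 0

    def test_best_hit_prefers_score_then_leftmost(self, ets_pwm):
        hits = pd.DataFrame({
            "region": ["a", "a", "a"], "start": [50, 10, 30],
            "strand": ["+", "+", "-"], "score": [8.1, 7.9, 8.1],
        })
        best = best_hits(hits)
        assert best.iloc[0]["start"] == 30


class TestPwm:
    def test_rows_must_sum_to_one(self):
        bad = np.full((6, 4), 0.3)
        with pytest.raises(ValueError):
            Pwm("bad", bad)

    def test_min_length_enforced(self):
        with pytest.raises(ValueError):
            Pwm.from_consensus("short", "ACG")

    def test_consensus_roundtrip(self, zic_pwm):
        assert zic_pwm.consensus == ZIC_CONSENSUS


@pytest.fixture(scope="module")
def genome():
    g, _, _ = generate_genome(GenomeSpec(chrom_length=400_000, seed=3))
    return g


class TestGcBackground:
    def test_gc_and_length_matching(self, genome):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 390_000, size=40)
        targets = pd.DataFrame({"chrom": "chr1", "start": starts,
                                "end": starts + 500})
        bed, seqs = sample_gc_matched_background(targets, genome, ratio=2,
                                                 seed=9)
        assert len(bed) == 80
        assert (bed["length"] == 500).all()
        tgc = np.mean([gc_fraction(genome["chr1"][s:e])
                       for s, e in zip(targets["start"], targets["end"])])
        bgc = np.mean([gc_fraction(s) for s in seqs.values()])
        assert abs(tgc - bgc) <= 0.02

    def test_background_avoids_targets(self, genome):
        targets = pd.DataFrame({"chrom": ["chr1"], "start": [1000],
                                "end": [2000]})
        bed, _ = sample_gc_matched_background(targets, genome, ratio=5,
                                              seed=1)
        assert not ((bed["start"] < 2000) & (bed["end"] > 1000)).any()

    def test_deterministic_per_seed(self, genome):
        targets = pd.DataFrame({"chrom": ["chr1"], "start": [5000],
                                "end": [5400]})
        b1, _ = sample_gc_matched_background(targets, genome, seed=7)
        b2, _ = sample_gc_matched_background(targets, genome, seed=7)
        pd.testing.assert_frame_equal(b1, b2)


class TestMotifEnrichment:
    def build_sets(self, pwm, frac_t, frac_b, n_t=60, n_b=120, seed=0):
        rng = np.random.default_rng(seed)
        targets = random_regions(rng, n_t)
        background = random_regions(rng, n_b)
        cons = pwm.consensus
        for i, (k, v) in enumerate(targets.items()):
            if i < frac_t * n_t:
                targets[k] = v[:100] + cons + v[100 + len(cons):]
        for i, (k, v) in enumerate(background.items()):
            if i < frac_b * n_b:
                background[k] = v[:100] + cons + v[100 + len(cons):]
        return targets, background

    def test_planted_enrichment_flagged(self, ets_pwm):
        t, b = self.build_sets(ets_pwm, 0.8, 0.1)
        res = motif_enrichment(t, b, [ets_pwm])
        assert res["fold"].iat[0] > 2
        assert res["significant"].iat[0]

    def test_equal_planting_not_flagged(self, ets_pwm):
        t, b = self.build_sets(ets_pwm, 0.5, 0.5)
        res = motif_enrichment(t, b, [ets_pwm])
        assert 0.8 <= res["fold"].iat[0] <= 1.25
        assert not res["significant"].iat[0]

    def test_empty_sets_rejected(self, ets_pwm):
        with pytest.raises(ValueError):
            motif_enrichment({}, {"a": "ACGT" * 30}, [ets_pwm])


class TestKmerEnrichment:
    def test_planted_kmer_ranks_first(self):
        rng = np.random.default_rng(6)
        targets = random_regions(rng, 40, length=120)
        background = random_regions(rng, 40, length=120)
        planted = "ACGTACGTAC"
        for i, k in enumerate(list(targets)[:24]):
            v = targets[k]
            targets[k] = v[:50] + planted + v[60:]
        table = kmer_enrichment(targets, background, k_values=(10,))
        top = table.iloc[0]
        assert top["kmer"] == min(planted, revcomp(planted))
        assert top["n_background"] <= 2

    def test_k_larger_than_region_errors(self):
        with pytest.raises(ValueError):
            kmer_enrichment({"a": "ACGTACGT"}, {"b": "ACGTACGT"},
                            k_values=(12,))


class TestCenterOnAnchor:
    def test_window_arithmetic_and_orientation(self, ets_pwm):
        rng = np.random.default_rng(80)
        seq = random_regions(rng, 1, length=600)["r0"]
        seq = seq[:300] + ets_pwm.consensus + seq[300 + len(ets_pwm):]
        centered, dropped = center_on_anchor({"x": seq}, ets_pwm, window=200)
        assert dropped == 0
        c = centered[0]
        assert len(c.seq) == 200
        assert c.anchor_center == 100
        start = c.anchor_center - len(ets_pwm) // 2
        assert c.seq[start : start + len(ets_pwm)] == ets_pwm.consensus

    def test_minus_strand_anchor_reoriented(self, ets_pwm):
        rng = np.random.default_rng(81)
        seq = random_regions(rng, 1, length=600)["r0"]
        seq = seq[:300] + revcomp(ets_pwm.consensus) + seq[300 + len(ets_pwm):]
        centered, _ = center_on_anchor({"x": seq}, ets_pwm, window=200)
        c = centered[0]
        assert c.anchor_strand == "-"
        start = c.anchor_center - len(ets_pwm) // 2
        assert c.seq[start : start + len(ets_pwm)] == ets_pwm.consensus

    def test_regions_without_anchor_dropped_and_counted(self, ets_pwm):
        rng = np.random.default_rng(10)
        seqs = random_regions(rng, 5, length=100)
        centered, dropped = center_on_anchor(seqs, ets_pwm, window=50)
        assert len(centered) + dropped == 5


class TestSpacingRecovery:
    @pytest.mark.parametrize("gap", [0, 2, 5, 10])
    @pytest.mark.parametrize("same", [True, False])
    def test_planted_gap_and_orientation_recovered(self, ets_pwm, zic_pwm,
                                                   gap, same):
        spec = MotifEmbeddingSpec(
            anchor_pwm=ets_pwm, query_pwm=zic_pwm, gap_bp=gap,
            same_orientation=same, n_regions=150, embed_fraction=0.8,
            seed=11)
        seqs, truth = embed_motif_pairs(spec)
        assert len(truth) == 120
        assert (truth["gap"] == gap).all()
        centered, _ = center_on_anchor(seqs, ets_pwm, window=1000)
        hist = spacing_histogram(centered, zic_pwm, len(ets_pwm),
                                 anchor_name="ETS")
        spikes = detect_spike(hist)
        bio = spikes[~spikes["overlap_artifact"]]
        top = bio.iloc[0]
        assert top["offset"] == spike_offset_for_gap(gap, len(ets_pwm),
                                                     len(zic_pwm))
        assert top["gap"] == gap
        assert top["orientation"] == ("same" if same else "opposite")

    def test_no_embedding_gives_flat_histogram(self, ets_pwm, zic_pwm):
        spec = MotifEmbeddingSpec(anchor_pwm=ets_pwm, query_pwm=zic_pwm,
                                  gap_bp=2, n_regions=80, embed_fraction=0.0,
                                  seed=12)
        seqs, truth = embed_motif_pairs(spec)
        assert len(truth) == 0
        centered, _ = center_on_anchor(seqs, ets_pwm, window=1000)
        if centered:
            hist = spacing_histogram(centered, zic_pwm, len(ets_pwm))
            spikes = detect_spike(hist)
            assert len(spikes[~spikes["overlap_artifact"]]) == 0


class TestOverlapArtifact:
    def test_query_sharing_anchor_prefix_flagged_as_artifact(self, ets_pwm):
        # degenerate query informative only at its AGG suffix, which
        # coincides with the anchor's AGG prefix: every anchored region
        # yields a query hit physically overlapping the anchor
        mat = np.vstack([np.full((5, 4), 0.25),
                         Pwm.from_consensus("x", "AGG" + "A").matrix[:3]])
        query = Pwm("agg_suffix", mat)
        rng = np.random.default_rng(13)
        seqs = {}
        bases = np.array(list("ACGT"))
        for i in range(80):
            s = "".join(bases[rng.integers(0, 4, 400)])
            seqs[f"r{i}"] = s[:200] + ets_pwm.consensus + s[200 + len(ets_pwm):]
        centered, _ = center_on_anchor(seqs, ets_pwm, window=300)
        hist = spacing_histogram(centered, query, len(ets_pwm),
                                 threshold=0.99 * query.max_score)
        spikes = detect_spike(hist)
        # the overlap spike is present and annotated
        artifacts = spikes[spikes["overlap_artifact"]]
        assert len(artifacts) > 0
        assert detect_spike(hist, exclude_overlap=True)["overlap_artifact"] \
            .eq(False).all()

    def test_flat_histogram_no_spikes(self, ets_pwm, zic_pwm):
        from crescape.motifs import SpacingHistogram

        table = pd.DataFrame({"offset": np.arange(-50, 51),
                              "same_count": 3, "opposite_count": 3,
                              "same_freq": 0.1, "opposite_freq": 0.1})
        hist = SpacingHistogram("a", "q", 8, 8, 30, table)
        assert len(detect_spike(hist)) == 0


class TestPairedModel:
    def build(self, ets_pwm, zic_pwm, gap=2, seed=14):
        spec = MotifEmbeddingSpec(anchor_pwm=ets_pwm, query_pwm=zic_pwm,
                                  gap_bp=gap, n_regions=120,
                                  embed_fraction=1.0, seed=seed)
        seqs, _ = embed_motif_pairs(spec)
        centered, _ = center_on_anchor(seqs, ets_pwm, window=1000)
        offset = spike_offset_for_gap(gap, len(ets_pwm), len(zic_pwm))
        return centered, offset

    def test_combined_length_and_gap(self, ets_pwm, zic_pwm):
        centered, offset = self.build(ets_pwm, zic_pwm, gap=2)
        model = build_paired_model(centered, ets_pwm, zic_pwm, offset)
        assert model.gap_bp == 2
        assert len(model.combined) == len(ets_pwm) + 2 + len(zic_pwm)
        # half-site columns are near-deterministic, gap columns near background
        info = -(model.combined.matrix *
                 np.log2(model.combined.matrix)).sum(axis=1)
        gap_cols = info[len(ets_pwm): len(ets_pwm) + 2]
        assert (gap_cols > 1.2).all()

    def test_zero_gap_length(self, ets_pwm, zic_pwm):
        centered, offset = self.build(ets_pwm, zic_pwm, gap=0)
        model = build_paired_model(centered, ets_pwm, zic_pwm, offset)
        assert len(model.combined) == len(ets_pwm) + len(zic_pwm)

    def test_insufficient_support_errors(self, ets_pwm, zic_pwm):
        centered, offset = self.build(ets_pwm, zic_pwm)
        with pytest.raises(ValueError, match="insufficient support"):
            build_paired_model(centered[:5], ets_pwm, zic_pwm, offset)


class TestEdgeGapArithmetic:
    @pytest.mark.parametrize("gap", [0, 1, 2, 5, 10])
    @pytest.mark.parametrize("la,lq", [(8, 8), (8, 6), (7, 9)])
    def test_offset_gap_roundtrip(self, gap, la, lq):
        off = spike_offset_for_gap(gap, la, lq)
        assert edge_gap(off, la, lq) == gap


class TestCountInstances:
    def test_planted_instances_counted(self, ets_pwm, zic_pwm):
        genome, _, _ = generate_genome(GenomeSpec(chrom_length=200_000,
                                                  seed=20))
        paired = ETS_CONSENSUS + "GT" + ZIC_CONSENSUS
        seq = list(genome["chr1"])
        rng = np.random.default_rng(21)
        spots = sorted(rng.choice(199_000, size=12, replace=False))
        spots = [s for i, s in enumerate(spots)
                 if i == 0 or s - spots[i - 1] > 100][:12]
        for s in spots:
            seq[s: s + len(paired)] = paired
        genome["chr1"] = "".join(seq)
        model = Pwm.from_consensus("pair", paired)
        n, bed = count_instances(genome, model,
                                 threshold=0.95 * model.max_score)
        assert n == len(spots)

    def test_threshold_above_max_counts_zero(self, ets_pwm):
        genome = {"chr1": ets_pwm.consensus * 10}
        n, _ = count_instances(genome, ets_pwm,
                               threshold=ets_pwm.max_score + 1)
        assert n == 0

    def test_minus_strand_instance_found(self, zic_pwm):
        rng = np.random.default_rng(22)
        bases = np.array(list("ACGT"))
        s = "".join(bases[rng.integers(0, 4, 5000)])
        s = s[:1000] + revcomp(zic_pwm.consensus) + s[1000 + len(zic_pwm):]
        n, bed = count_instances({"chr1": s}, zic_pwm,
                                 threshold=0.95 * zic_pwm.max_score)
        assert ((bed["start"] == 1000) & (bed["strand"] == "-")).any()
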