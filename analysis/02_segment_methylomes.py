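#!/usr/bin/env python
"""Segment each subtype's methylome into UMRs, LMRs, and DMVs.

Pools the two replicates per subtype, segments at the m < 0.3 smoothed
threshold, classifies regions by CpG count (>= 30 CpGs: UMR, else LMR),
promotes UMRs longer than 3 kb to DMVs, and scores recovery against the
planted truth blocks at >= 50% reciprocal overlap. Tables land in
results/segmentation/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results" / "segmentation"


def main() -> None:
    from crescape import io as cio
    from crescape.intervals import reciprocal_overlap_scores
    from crescape.methylome import segment_classify
    from crescape.pipeline import _load_tracks

    if not (STUDY / "manifest.tsv").exists():
        sys.exit("run analysis/01_simulate_study.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    pooled, _ = _load_tracks(STUDY / "manifest.tsv")
    umr_truth = pd.read_csv(STUDY / "truth" / "umr_blocks.tsv", sep="\t")
    lmr_truth = pd.read_csv(STUDY / "truth" / "lmr_blocks.tsv", sep="\t")
    dmr_truth = pd.read_csv(STUDY / "truth" / "dmr_blocks.tsv", sep="\t")
    dmv_truth = umr_truth[umr_truth["end"] - umr_truth["start"] > 3000]

    rows = []
    for subtype, track in pooled.items():
        regions = segment_classify(track)
        regions.to_csv(OUT / f"segments_{subtype}.tsv", sep="\t", index=False)
        cio.write_bed(cio.region_bed_with_class(regions),
                      OUT / f"segments_{subtype}.bed")
        own = dmr_truth[dmr_truth["subtype"] == subtype]
        umr_t = pd.concat([umr_truth, own[["chrom", "start", "end"]]])
        u = reciprocal_overlap_scores(regions[regions["klass"] == "UMR"], umr_t)
        l = reciprocal_overlap_scores(regions[regions["klass"] == "LMR"],
                                      lmr_truth)
        d = reciprocal_overlap_scores(regions[regions["is_dmv"]], dmv_truth)
        rows.append({
            "subtype": subtype,
            "n_umr": int((regions["klass"] == "UMR").sum()),
            "n_lmr": int((regions["klass"] == "LMR").sum()),
            "n_dmv": int(regions["is_dmv"].sum()),
            "umr_median_mcg": round(float(
                regions.loc[regions["klass"] == "UMR", "mean_mcg"].median()), 3),
            "lmr_median_mcg": round(float(
                regions.loc[regions["klass"] == "LMR", "mean_mcg"].median()), 3),
            "umr_recall": round(u["recall"], 3),
            "umr_precision": round(u["precision"], 3),
            "lmr_recall": round(l["recall"], 3),
            "lmr_precision": round(l["precision"], 3),
            "dmv_recall": round(d["recall"], 3),
            "dmv_precision": round(d["precision"], 3),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "recovery_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print("\nUMRs sit at ~10% mCG on CpG islands, LMRs at ~15% in CpG-poor "
          "background; all recovery metrics vs planted truth at >=50% "
          "reciprocal overlap.")


if __name__ == "__main__":
    sys.exit(main())
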