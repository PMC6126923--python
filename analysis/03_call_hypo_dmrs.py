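#!/usr/bin/env python
"""Call differentially hypomethylated regions across the four EC subtypes.

Runs the Monte-Carlo RMS homogeneity test at every covered CpG across
the subtype-pooled methylomes, chains significant sites into hypo-DMRs,
requires hypomethylation in both replicates, assigns subtype-unique
(ECTS) hypo-DMR sets, merges nearby ECTS-hypo-DMRs into large hypo-DMRs,
and scores recovery against the planted blocks. Tables land in
results/dmr/.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results" / "dmr"
SEED = 7


def main() -> None:
    from crescape.dmr import (assign_ects_hypo_dmrs, call_dmrs,
                              merge_large_hypo_dmrs,
                              require_replicate_support)
    from crescape.intervals import reciprocal_overlap_scores
    from crescape.pipeline import _load_tracks

    if not (STUDY / "manifest.tsv").exists():
        sys.exit("run analysis/01_simulate_study.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    warnings.filterwarnings("ignore", category=UserWarning)
    pooled, replicate_tracks = _load_tracks(STUDY / "manifest.tsv")
    truth = pd.read_csv(STUDY / "truth" / "dmr_blocks.tsv", sep="\t")

    dmrs = call_dmrs(pooled, seed=SEED)
    dmrs = require_replicate_support(dmrs, replicate_tracks)
    dmrs.to_csv(OUT / "hypo_dmrs.tsv", sep="\t", index=False)
    all_hypo, ects = assign_ects_hypo_dmrs(dmrs, list(pooled))

    rows = []
    for subtype in pooled:
        e = ects[subtype]
        e.to_csv(OUT / f"ects_hypo_dmrs_{subtype}.tsv", sep="\t", index=False)
        large = merge_large_hypo_dmrs(e)
        large.to_csv(OUT / f"large_hypo_dmrs_{subtype}.tsv", sep="\t",
                     index=False)
        planted = truth[truth["subtype"] == subtype]
        sc = reciprocal_overlap_scores(e, planted)
        rows.append({"subtype": subtype, "n_all_hypo": len(all_hypo[subtype]),
                     "n_ects": len(e), "n_large": len(large),
                     "recall": round(sc["recall"], 3),
                     "precision": round(sc["precision"], 3)})
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "recovery_summary.tsv", sep="\t", index=False)
    print(f"{len(dmrs)} replicate-supported hypo-DMRs\n")
    print(summary.to_string(index=False))
    print("\nEach subtype's ECTS set contains DMRs uniquely hypomethylated "
          "in that subtype; recovery scored against planted 1 kb blocks at "
          ">=50% reciprocal overlap.")


if __name__ == "__main__":
    sys.exit(main())
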