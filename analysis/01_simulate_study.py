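#!/usr/bin/env python
"""Generate the synthetic endothelial-cell regulatory study.

Writes a 2 Mb genome with CpG islands, four EC subtypes x two replicate
methylomes (planted UMR/LMR/DMV blocks, subtype-unique hypo-DMR blocks),
jittered replicate peak sets, an expression table with planted
EC-enriched / tissue-specific genes, candidate-CRE sequences carrying
the paired ETS:ZIC element at a 2 bp gap, and truth tables for scoring
every downstream caller. All inputs land in results/study/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
SEED = 7


def main() -> None:
    from crescape.pipeline import build_demo_inputs

    setup = build_demo_inputs(STUDY, seed=SEED)
    truth = setup["truth"]
    truth_dir = STUDY / "truth"
    truth_dir.mkdir(exist_ok=True)
    for key in ("umr_blocks", "lmr_blocks", "dmr_blocks", "motif_pairs",
                "peaks"):
        truth[key].to_csv(truth_dir / f"{key}.tsv", sep="\t", index=False)
    (truth_dir / "expression_truth.json").write_text(json.dumps(
        {k: sorted(v) if isinstance(v, set)
         else {s: sorted(g) for s, g in v.items()}
         for k, v in truth["expression"].items()}, indent=2))
    (truth_dir / "planted.json").write_text(json.dumps({
        "planted_gap_bp": truth["planted_gap"],
        "n_planted_genome_pairs": truth["n_planted_genome_pairs"],
    }, indent=2))

    print(f"study written to {STUDY}")
    print(f"  genome: 1 chromosome, "
          f"{len(open(STUDY / 'manifest.tsv').readlines()) - 1} methylome tracks")
    print(f"  planted: {len(truth['umr_blocks'])} UMR blocks "
          f"({(truth['umr_blocks']['end'] - truth['umr_blocks']['start'] > 3000).sum()} DMV-sized), "
          f"{len(truth['lmr_blocks'])} LMR blocks, "
          f"{len(truth['dmr_blocks'])} subtype-unique hypo-DMR blocks")
    print(f"  paired ETS:ZIC element: gap {truth['planted_gap']} bp in CRE "
          f"regions; {truth['n_planted_genome_pairs']} genome-wide instances")


if __name__ == "__main__":
    sys.exit(main())
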