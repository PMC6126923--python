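"""Transcript filter cascades for endothelial-enriched and tissue-specific genes.

Input is a wide per-gene table of TPM quantifications from FACS-sorted
GFP-positive (endothelial) and GFP-negative (parenchymal) fractions of
each tissue, with precomputed fold changes and posterior probabilities
of differential expression (PPDE) from an empirical-Bayes model; those
statistics are consumed, not fitted, here.

Column schema (subtypes are free-form labels, replicates 1..R):

- ``gene``, ``biotype``
- ``tpm_<subtype>_<pos|neg>_<rep>``
- ``fold_pos_neg_<subtype>``, ``ppde_pos_neg_<subtype>``
- ``fold_<s>_vs_<o>``, ``ppde_<s>_vs_<o>`` for ordered subtype pairs

The cascade: EC-enriched (>= 2-fold GFP+ over GFP-, PPDE >= 0.95,
TPM >= 10 in both replicates, per tissue; union over tissues), then
EC tissue-specific genes (ECTSGs: EC-enriched and >= 2-fold over every
other subtype with PPDE >= 0.95), plus the strict >2-fold GFP-negative
exclusion list used to purge parenchymal transcripts from single-cell
high-dispersion gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FilterThresholds:
    min_fold: float = 2.0
    min_ppde: float = 0.95
    min_tpm: float = 10.0

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")


def _replicate_cols(table: pd.DataFrame, subtype: str, fraction: str) -> list[str]:
    prefix = f"tpm_{subtype}_{fraction}_"
    cols = [c for c in table.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"no TPM columns for {subtype}/{fraction}")
    return sorted(cols)


def naive_fold(num: pd.Series, den: pd.Series, pseudocount: float = 1.0) -> pd.Series:
    """(mean TPM + pseudocount) ratio — a labeled stand-in when model
    folds are absent; NOT equivalent to the empirical-Bayes posterior fold."""
    return (num + pseudocount) / (den + pseudocount)


def ec_enriched(
    table: pd.DataFrame, subtype: str, t: FilterThresholds | None = None
) -> pd.Series:
    """Per-gene EC-enrichment flag for one tissue.

    True iff GFP+/GFP- fold >= min_fold, PPDE >= min_ppde, and TPM in
    the GFP-positive fraction >= min_tpm in EVERY replicate.
    """
    t = t or FilterThresholds()
    pos_cols = _replicate_cols(table, subtype, "pos")
    bad = table[pos_cols].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"missing replicate TPMs for genes: "
            f"{table.loc[bad, 'gene'].head(5).tolist()}"
        )
    fold = table[f"fold_pos_neg_{subtype}"]
    ppde = table[f"ppde_pos_neg_{subtype}"]
    tpm_ok = (table[pos_cols] >= t.min_tpm).all(axis=1)
    return (fold >= t.min_fold) & (ppde >= t.min_ppde) & tpm_ok


def ec_enriched_union(
    table: pd.DataFrame, subtypes: list[str], t: FilterThresholds | None = None
) -> set[str]:
    """Union over tissues of the per-tissue EC-enriched transcript sets."""
    flags = np.zeros(len(table), dtype=bool)
    for s in subtypes:
        flags |= ec_enriched(table, s, t).to_numpy()
    return set(table.loc[flags, "gene"])


def differential_between_subtypes(
    table: pd.DataFrame,
    subtype: str,
    others: list[str],
    t: FilterThresholds | None = None,
) -> pd.Series:
    """Tissue-specific differential flag for EC-enriched genes.

    True iff the gene is EC-enriched in `subtype` and, versus EVERY
    other subtype, fold >= min_fold and PPDE >= min_ppde, with
    TPM >= min_tpm in both replicates of `subtype`.
    """
    t = t or FilterThresholds()
    flag = ec_enriched(table, subtype, t)
    pos_cols = _replicate_cols(table, subtype, "pos")
    flag &= (table[pos_cols] >= t.min_tpm).all(axis=1)
    for o in others:
        fcol, pcol = f"fold_{subtype}_vs_{o}", f"ppde_{subtype}_vs_{o}"
        if fcol not in table.columns or pcol not in table.columns:
            raise ValueError(f"missing pair statistics {fcol}/{pcol}")
        flag &= (table[fcol] >= t.min_fold) & (table[pcol] >= t.min_ppde)
    return flag


def call_ectsgs(
    table: pd.DataFrame,
    subtypes: list[str],
    t: FilterThresholds | None = None,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Per-subtype EC tissue-specific gene sets plus a biotype tally.

    Sets are disjoint across subtypes (a gene >= 2-fold above every other
    subtype in S cannot simultaneously satisfy that in another subtype);
    disjointness is asserted, not assumed.
    """
    ectsg: dict[str, set[str]] = {}
    for s in subtypes:
        others = [o for o in subtypes if o != s]
        flag = differential_between_subtypes(table, s, others, t)
        ectsg[s] = set(table.loc[flag, "gene"])
    for i, a in enumerate(subtypes):
        for b in subtypes[i + 1 :]:
            both = ectsg[a] & ectsg[b]
            if both:
                raise AssertionError(
                    f"gene(s) tissue-specific for both {a} and {b}: {sorted(both)[:5]}"
                )
    tally_rows = []
    by_gene = table.set_index("gene")
    for s in subtypes:
        counts = by_gene.loc[sorted(ectsg[s]), "biotype"].value_counts() \
            if ectsg[s] else pd.Series(dtype=int)
        tally_rows.append({"subtype": s, "n": len(ectsg[s]),
                           **counts.to_dict()})
    return ectsg, pd.DataFrame(tally_rows).fillna(0)


def non_ec_exclusion_list(
    table: pd.DataFrame, tissue: str, fold: float = 2.0
) -> set[str]:
    """Genes enriched strictly >`fold` in the GFP-negative fraction.

    Intended to be subtracted from single-cell high-dispersion gene
    lists: transcripts abundant in the parenchymal (GFP-negative)
    fraction likely contaminate EC single-cell profiles. Uses the
    ``fold_neg_pos_<tissue>`` column when present, otherwise the
    pseudocount fold of replicate-mean TPMs.
    """
    col = f"fold_neg_pos_{tissue}"
    if col in table.columns:
        f = table[col]
    else:
        neg = table[_replicate_cols(table, tissue, "neg")].mean(axis=1)
        pos = table[_replicate_cols(table, tissue, "pos")].mean(axis=1)
        f = naive_fold(neg, pos)
    return set(table.loc[f > fold, "gene"])


def run_cascade(
    table: pd.DataFrame,
    subtypes: list[str],
    t: FilterThresholds | None = None,
) -> dict:
    """Full filter cascade with the nesting invariant checked.

    Returns the EC-enriched union, per-subtype differential sets and
    ECTSG sets, and the biotype tally; raises if
    ECTSG(S) ⊆ differential(S) ⊆ EC-enriched ever fails.
    """
    t = t or FilterThresholds()
    enriched = ec_enriched_union(table, subtypes, t)
    ectsg, tally = call_ectsgs(table, subtypes, t)
    differential = {}
    for s in subtypes:
        others = [o for o in subtypes if o != s]
        flag = differential_between_subtypes(table, s, others, t)
        differential[s] = set(table.loc[flag, "gene"])
        if not ectsg[s] <= differential[s]:
            raise AssertionError(f"ECTSG({s}) not nested in differential({s})")
        if not differential[s] <= enriched:
            raise AssertionError(f"differential({s}) not nested in EC-enriched union")
    return {
        "ec_enriched": enriched,
        "differential": differential,
        "ectsg": ectsg,
        "biotype_tally": tally,
    }
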