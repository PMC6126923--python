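"""Interval arithmetic and overlap statistics for BED-style feature sets.

Feature sets are pandas DataFrames with at least ``chrom``, ``start``,
``end`` columns (0-based half-open, BED convention), optionally
``strand``, ``name``, ``score``. Overlap means >= 1 bp of shared
half-open extent; abutting intervals ([a,b) and [b,c)) never overlap.

The enrichment statistic is the exact hypergeometric upper tail used for
feature-category versus gene-category overlap testing, with all four
counting arguments explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _require_columns(df: pd.DataFrame, cols=("chrom", "start", "end")) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"interval table missing columns: {missing}")


def _trees_by_chrom(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        tree = IntervalTree()
        for start, end in zip(sub["start"], sub["end"]):
            if start < end:
                tree.addi(int(start), int(end))
        trees[str(chrom)] = tree
    return trees


def intersect_any(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Rows of `a` overlapping at least one interval of `b` by >= 1 bp.

    Mirrors ``bedtools intersect -u``: each row of `a` is returned at
    most once regardless of how many `b` intervals it touches.
    """
    _require_columns(a)
    _require_columns(b)
    trees = _trees_by_chrom(b)
    orphans = set(a["chrom"].unique()) - set(trees)
    if orphans and len(trees):
        warnings.warn(
            f"chromosomes in query absent from subject set: {sorted(orphans)}",
            stacklevel=2,
        )
    keep = [
        chrom in trees and bool(trees[chrom].overlap(start, end))
        for chrom, start, end in zip(a["chrom"].astype(str), a["start"], a["end"])
    ]
    return a.loc[keep]


def shared_across(sets: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Annotate each set's intervals with their sharing degree.

    Returns a copy of every input set with columns ``n_shared`` (how many
    *other* sets contain an overlapping interval), ``fully_shared``
    (overlaps every other set) and ``specific`` (overlaps none).
    """
    if len(sets) < 2:
        raise ValueError("need at least two feature sets")
    trees = [_trees_by_chrom(s) for s in sets]
    out = []
    for i, s in enumerate(sets):
        _require_columns(s)
        others = [t for j, t in enumerate(trees) if j != i]
        n_shared = []
        for chrom, start, end in zip(s["chrom"].astype(str), s["start"], s["end"]):
            n = sum(
                1
                for t in others
                if chrom in t and bool(t[chrom].overlap(int(start), int(end)))
            )
            n_shared.append(n)
        annotated = s.copy()
        annotated["n_shared"] = n_shared
        annotated["fully_shared"] = annotated["n_shared"] == len(others)
        annotated["specific"] = annotated["n_shared"] == 0
        out.append(annotated)
    return out


def nearest_tss(
    features: pd.DataFrame, tss: pd.DataFrame, promoter_dist: int = 2000
) -> pd.DataFrame:
    """Unsigned distance from each feature to its nearest TSS.

    `tss` needs columns ``chrom`` and ``pos`` (single-bp, strand already
    resolved). Distance is 0 when the feature contains the TSS, else the
    bp gap from the nearest covered base. Features closer than
    `promoter_dist` are classed ``proximal``, the rest ``distal``; ties
    go to the first TSS in coordinate order.
    """
    _require_columns(features)
    if len(tss) == 0:
        raise ValueError("empty TSS table")
    out = features.copy()
    dists = np.empty(len(features), dtype=float)
    nearest = np.empty(len(features), dtype=object)
    by_chrom = {
        str(c): sub.sort_values("pos").reset_index(drop=True)
        for c, sub in tss.groupby("chrom", sort=False)
    }
    for i, (chrom, start, end) in enumerate(
        zip(features["chrom"].astype(str), features["start"], features["end"])
    ):
        sub = by_chrom.get(chrom)
        if sub is None or len(sub) == 0:
            dists[i] = np.inf
            nearest[i] = None
            continue
        pos = sub["pos"].to_numpy()
        d = np.where(
            (pos >= start) & (pos < end),
            0,
            np.where(pos < start, start - pos, pos - (end - 1)),
        )
        j = int(np.argmin(d))  # argmin takes the first = leftmost TSS on ties
        dists[i] = d[j]
        nearest[i] = sub["name"].iat[j] if "name" in sub.columns else str(pos[j])
    out["tss_dist"] = dists
    out["nearest_tss"] = nearest
    out["tss_class"] = np.where(dists < promoter_dist, "proximal", "distal")
    return out


def within_window(
    features: pd.DataFrame, genes: pd.DataFrame, gene_window: int = 100_000
) -> pd.DataFrame:
    """Feature-gene pairs where the feature lies within `gene_window` bp.

    Mirrors ``bedtools window -w``: a pair (f, g) is emitted iff f
    overlaps [g.start - w, g.end + w). A feature may pair with many
    genes and vice versa.
    """
    _require_columns(features)
    _require_columns(genes)
    rows = []
    gene_trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        tree = IntervalTree()
        for idx, start, end in zip(sub.index, sub["start"], sub["end"]):
            tree.addi(max(0, int(start) - gene_window), int(end) + gene_window, idx)
        gene_trees[str(chrom)] = tree
    for fidx, chrom, start, end in zip(
        features.index, features["chrom"].astype(str), features["start"], features["end"]
    ):
        tree = gene_trees.get(chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(start), int(end)), key=lambda h: h.data):
            rows.append((fidx, hit.data))
    pairs = pd.DataFrame(rows, columns=["feature_index", "gene_index"])
    if len(pairs):
        pairs = pairs.merge(
            features.add_prefix("feature_"), left_on="feature_index", right_index=True
        ).merge(genes.add_prefix("gene_"), left_on="gene_index", right_index=True)
    return pairs.reset_index(drop=True)


def consensus_peaks(
    replicate_sets: list[pd.DataFrame], consensus_min_frac: float = 0.66
) -> pd.DataFrame:
    """Union-merge replicate peaks; keep regions supported by enough replicates.

    All peaks are unioned into merged regions (overlapping or abutting
    intervals coalesce); a merged region is retained iff peaks from at
    least ``ceil(consensus_min_frac * R)`` distinct replicates fall in
    it. With the 0.66 default this is the 2-of-2 / 2-of-3 replicate rule.
    """
    r = len(replicate_sets)
    if r < 2:
        raise ValueError("need at least two replicate peak sets")
    need = int(np.ceil(consensus_min_frac * r))
    pooled = []
    for rep_id, s in enumerate(replicate_sets):
        _require_columns(s)
        sub = s[["chrom", "start", "end"]].copy()
        sub["replicate"] = rep_id
        pooled.append(sub)
    allpeaks = pd.concat(pooled).sort_values(["chrom", "start", "end"])
    rows = []
    for chrom, sub in allpeaks.groupby("chrom", sort=False):
        cur_start = cur_end = None
        members: set[int] = set()
        for start, end, rep in zip(sub["start"], sub["end"], sub["replicate"]):
            if cur_end is None or start > cur_end:  # gap > 0: close region
                if cur_end is not None and len(members) >= need:
                    rows.append((chrom, cur_start, cur_end, len(members)))
                cur_start, cur_end, members = start, end, {rep}
            else:
                cur_end = max(cur_end, end)
                members.add(rep)
        if cur_end is not None and len(members) >= need:
            rows.append((chrom, cur_start, cur_end, len(members)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_replicates"])


def filter_fragments(fragments: pd.DataFrame, max_fragment: int = 100) -> pd.DataFrame:
    """Retain sequencing fragments strictly shorter than `max_fragment` bp.

    Sub-100 bp fragments are enriched for nucleosome-free regions and are
    the substrate for accessible-chromatin peak analysis here.
    """
    if "length" not in fragments.columns:
        fragments = fragments.assign(length=fragments["end"] - fragments["start"])
    if (fragments["length"] < 0).any():
        raise ValueError("negative fragment lengths")
    return fragments[fragments["length"] < max_fragment]


@dataclass(frozen=True)
class OverlapEnrichmentQuery:
    """Arguments of the hypergeometric overlap test, hygecdf-style.

    k: tested-category features overlapping the gene category
    n: sample size of the tested feature category (draws)
    K: all features overlapping the gene category (successes in population)
    N: universe size (population)
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        for field in ("k", "n", "K", "N"):
            v = getattr(self, field)
            if v < 0:
                raise ValueError(f"{field} must be non-negative, got {v}")
        if self.k > min(self.n, self.K):
            raise ValueError(f"k={self.k} exceeds min(n={self.n}, K={self.K})")
        if self.K > self.N:
            raise ValueError(f"K={self.K} exceeds N={self.N}")
        if self.n > self.N:
            raise ValueError(f"n={self.n} exceeds N={self.N}")


def hypergeom_upper(q: OverlapEnrichmentQuery) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if q.k == 0:
        return 1.0
    return float(hypergeom.sf(q.k - 1, q.N, q.K, q.n))


def reciprocal_overlap_scores(
    called: pd.DataFrame, truth: pd.DataFrame, min_frac: float = 0.5
) -> dict:
    """Recall/precision of called intervals against a truth set.

    A truth interval is recovered when some called interval overlaps it
    reciprocally by >= `min_frac` of both lengths; a called interval is
    a true positive when it so matches some truth interval.
    """
    _require_columns(called)
    _require_columns(truth)

    def matches(x: pd.DataFrame, y_trees: dict, y: pd.DataFrame) -> int:
        n = 0
        y_lookup = {
            (r["chrom"], r["start"], r["end"]): r["end"] - r["start"]
            for _, r in y.iterrows()
        }
        for chrom, start, end in zip(x["chrom"].astype(str), x["start"], x["end"]):
            tree = y_trees.get(chrom)
            if tree is None:
                continue
            xlen = end - start
            for hit in tree.overlap(int(start), int(end)):
                ov = min(end, hit.end) - max(start, hit.begin)
                ylen = hit.end - hit.begin
                if ov >= min_frac * xlen and ov >= min_frac * ylen:
                    n += 1
                    break
        return n

    truth_trees = _trees_by_chrom(truth)
    called_trees = _trees_by_chrom(called)
    tp_called = matches(called, truth_trees, truth)
    recovered = matches(truth, called_trees, called)
    recall = recovered / len(truth) if len(truth) else float("nan")
    precision = tp_called / len(called) if len(called) else float("nan")
    return {"recall": recall, "precision": precision,
            "n_called": len(called), "n_truth": len(truth)}


def overlap_enrichment(
    tested: pd.DataFrame,
    universe: pd.DataFrame,
    gene_category: pd.DataFrame,
    label: str = "",
) -> dict:
    """Hypergeometric enrichment of a feature category's overlap with genes.

    Counts follow the published argument form: k = tested features
    overlapping the gene category, n = size of the tested category,
    K = universe features overlapping the gene category, N = universe
    size.
    """
    k = len(intersect_any(tested, gene_category))
    K = len(intersect_any(universe, gene_category))
    q = OverlapEnrichmentQuery(k=k, n=len(tested), K=K, N=len(universe))
    p = hypergeom_upper(q)
    return {
        "label": label,
        "k": q.k,
        "n": q.n,
        "K": q.K,
        "N": q.N,
        "p": p,
        "neg_log10_p": float(-np.log10(p)) if p > 0 else np.inf,
    }
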