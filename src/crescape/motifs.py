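"""PWM scanning, motif enrichment, and paired-motif spacing analysis.

The spacing machinery recovers composite transcription-factor elements:
regions are centered and oriented on the best hit of an anchor motif
(e.g. an ETS-family motif), query-motif hits are accumulated into a
1-bp-bin histogram of center-to-center offsets split by relative
orientation, spikes are detected robustly, and the sequences under a
spike are stacked into a combined paired-motif model whose half-site
gap (unoccupied bp between anchor 3' end and query 5' start) is
reported alongside the center offset.

Sequences are plain A/C/G/T/N strings; region sets are ``dict[str, str]``
mapping region id to sequence. All scanning is log-odds on both strands;
N contributes the background score (log-odds 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

_COMP = str.maketrans("ACGTN", "TGCAN")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
UNIFORM_BG = np.full(4, 0.25)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, 4) for b in seq.upper()), dtype=np.int8,
                       count=len(seq))


@dataclass
class Pwm:
    """Position weight matrix over {A, C, G, T} with a scanning threshold.

    `matrix` is (L, 4) position probabilities; `threshold_frac` sets the
    default hit threshold as a fraction of the maximal attainable
    log-odds score.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    threshold_frac: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be (L, 4)")
        if len(self.matrix) < 4:
            raise ValueError("motif length must be >= 4")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-6):
            raise ValueError("each matrix row must sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    @classmethod
    def from_consensus(cls, name: str, consensus: str, certainty: float = 0.97,
                       **kw) -> "Pwm":
        """PWM from a consensus string; off-consensus bases share 1-certainty."""
        mat = np.full((len(consensus), 4), (1 - certainty) / 3)
        for i, b in enumerate(consensus.upper()):
            mat[i, _CODE[b]] = certainty
        return cls(name, mat, **kw)

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log2-odds lookup; column 4 (N) scores 0."""
        lo = np.zeros((len(self.matrix), 5))
        lo[:, :4] = np.log2(np.maximum(self.matrix, 1e-9) / self.background)
        return lo

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    def default_threshold(self) -> float:
        return self.threshold_frac * self.max_score

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.name + "_rc", self.matrix[::-1, ::-1].copy(),
                   self.background.copy(), self.threshold_frac)


def _scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score of every window start; empty if sequence too short."""
    L = len(lo)
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    out = np.zeros(n)
    for j in range(L):
        out += lo[j, codes[j : j + n]]
    return out


def scan(
    sequences: dict[str, str], pwm: Pwm, threshold: float | None = None
) -> pd.DataFrame:
    """Score both strands of every region; report hits >= threshold.

    Minus-strand hits are reported at the plus-strand coordinate of the
    match (start of the occupied window). Overlapping hits are allowed.
    """
    thr = pwm.default_threshold() if threshold is None else threshold
    lo_fwd = pwm.log_odds
    lo_rev = pwm.reverse_complement().log_odds
    rows = []
    for rid, seq in sequences.items():
        codes = encode(seq)
        if len(codes) < len(pwm):
            continue  # region shorter than motif: skipped
        for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
            s = _scores(codes, lo)
            for i in np.flatnonzero(s >= thr):
                rows.append((rid, int(i), strand, float(s[i])))
    return pd.DataFrame(rows, columns=["region", "start", "strand", "score"])


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Best-scoring hit per region, ties broken leftmost then plus strand."""
    if len(hits) == 0:
        return hits
    ordered = hits.sort_values(["region", "score", "start", "strand"],
                               ascending=[True, False, True, True])
    return ordered.groupby("region", sort=False).head(1).reset_index(drop=True)


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0


def sample_gc_matched_background(
    targets: pd.DataFrame,
    genome: dict[str, str],
    gc_bin_width: float = 0.05,
    ratio: int = 2,
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Length- and GC-matched random genomic regions avoiding the targets.

    For each target, `ratio` regions of identical length are drawn
    uniformly from the genome, accepted when their GC content falls in
    the same `gc_bin_width` bin and they overlap no target; after
    `max_tries` rejections the bin constraint relaxes to adjacent bins
    (tallied in the returned frame's ``relaxed`` column).
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    target_iv = {
        c: sub[["start", "end"]].to_numpy()
        for c, sub in targets.groupby("chrom", sort=False)
    }
    rows, seqs = [], {}
    for _, t in targets.iterrows():
        tlen = int(t["end"] - t["start"])
        tseq = genome[t["chrom"]][int(t["start"]): int(t["end"])]
        tbin = int(gc_fraction(tseq) / gc_bin_width)
        for j in range(ratio):
            relaxed = 0
            for trial in range(max_tries * 2):
                ci = rng.choice(len(chroms), p=probs)
                chrom = chroms[ci]
                if len(genome[chrom]) < tlen:
                    continue
                start = int(rng.integers(0, len(genome[chrom]) - tlen + 1))
                end = start + tlen
                iv = target_iv.get(chrom)
                if iv is not None and np.any((iv[:, 0] < end) & (iv[:, 1] > start)):
                    continue
                seq = genome[chrom][start:end]
                gbin = int(gc_fraction(seq) / gc_bin_width)
                tol = 0 if trial < max_tries else 1  # relax to adjacent bin
                if abs(gbin - tbin) <= tol:
                    relaxed = tol
                    rid = f"bg_{len(rows)}"
                    rows.append((rid, chrom, start, end, tlen, relaxed))
                    seqs[rid] = seq
                    break
            else:
                raise RuntimeError("background sampling exhausted retries")
    bed = pd.DataFrame(rows, columns=["name", "chrom", "start", "end",
                                      "length", "relaxed"])
    return bed, seqs


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    q[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(q, 1.0)


def motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwms: list[Pwm],
    q_max: float = 0.001,
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Region-presence enrichment of each motif in targets vs background.

    fold = (% targets with >= 1 hit) / (% background with >= 1 hit);
    p is the exact hypergeometric upper tail on region presence counts;
    q is Benjamini-Hochberg across motifs. Significant iff q < q_max
    (strict) and fold > fold_min (strict).
    """
    if not target_seqs or not background_seqs:
        raise ValueError("both region sets must be non-empty")
    nt, nb = len(target_seqs), len(background_seqs)
    rows = []
    for pwm in pwms:
        kt = len(scan(target_seqs, pwm)["region"].unique())
        kb = len(scan(background_seqs, pwm)["region"].unique())
        pct_t, pct_b = 100 * kt / nt, 100 * kb / nb
        fold = pct_t / pct_b if pct_b > 0 else np.inf
        p = float(hypergeom.sf(kt - 1, nt + nb, kt + kb, nt)) if kt > 0 else 1.0
        rows.append((pwm.name, kt, kb, pct_t, pct_b, fold, p))
    out = pd.DataFrame(rows, columns=["motif", "n_target", "n_background",
                                      "pct_target", "pct_background", "fold", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["q"] < q_max) & (out["fold"] > fold_min)
    return out


def kmer_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    k_values: tuple[int, ...] = (8, 10, 12),
    top_n: int = 25,
) -> pd.DataFrame:
    """Exhaustive k-mer region-presence enrichment (de novo stand-in).

    k-mers are canonicalized over strands (lexicographic min of k-mer
    and reverse complement) and counted by region presence; the exact
    hypergeometric upper tail ranks them, BH-adjusted within each k.
    """
    min_len = min(len(s) for s in list(target_seqs.values()) +
                  list(background_seqs.values()))
    for k in k_values:
        if k > min_len:
            raise ValueError(f"k={k} exceeds shortest region length {min_len}")
    nt, nb = len(target_seqs), len(background_seqs)

    def presence(seqs: dict[str, str], k: int) -> dict[str, int]:
        counts: dict[str, int] = {}
        for seq in seqs.values():
            seq = seq.upper()
            seen = set()
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                seen.add(min(kmer, revcomp(kmer)))
            for kmer in seen:
                counts[kmer] = counts.get(kmer, 0) + 1
        return counts

    frames = []
    for k in k_values:
        pt = presence(target_seqs, k)
        pb = presence(background_seqs, k)
        rows = []
        for kmer, kt in pt.items():
            kb = pb.get(kmer, 0)
            fold = (kt / nt) / (kb / nb) if kb > 0 else np.inf
            p = float(hypergeom.sf(kt - 1, nt + nb, kt + kb, nt))
            rows.append((k, kmer, kt, kb, fold, p))
        sub = pd.DataFrame(rows, columns=["k", "kmer", "n_target",
                                          "n_background", "fold", "p"])
        if len(sub):
            sub["q"] = bh_adjust(sub["p"].to_numpy())
            sub = sub.sort_values(["p", "kmer"]).head(top_n)
        frames.append(sub)
    return pd.concat(frames).reset_index(drop=True)


@dataclass
class CenteredRegion:
    """A region re-coordinated and oriented on its best anchor-motif hit."""

    region: str
    seq: str              # oriented: anchor is on the + strand of this string
    anchor_center: int    # index of the anchor motif center within `seq`
    anchor_strand: str    # anchor hit strand in the original region
    anchor_score: float


def center_on_anchor(
    sequences: dict[str, str],
    anchor: Pwm,
    window: int = 1000,
    threshold: float | None = None,
) -> tuple[list[CenteredRegion], int]:
    """Center each region on its best anchor hit and orient it.

    Returns centered regions plus the count of regions dropped for
    having no anchor hit. The extracted window spans
    [center - window/2, center + window/2) of the original region,
    N-padded past region ends, then reverse-complemented when the
    anchor hit is on the minus strand so the anchor always reads on the
    oriented plus strand.
    """
    hits = scan(sequences, anchor, threshold)
    best = best_hits(hits)
    half = window // 2
    la = len(anchor)
    out = []
    for _, h in best.iterrows():
        seq = sequences[h["region"]].upper()
        center = int(h["start"]) + la // 2
        lo, hi = center - half, center + half
        padded = ("N" * max(0, -lo)) + seq[max(0, lo):min(len(seq), hi)] \
            + ("N" * max(0, hi - len(seq)))
        anchor_center = center - lo
        if h["strand"] == "-":
            padded = revcomp(padded)
            # recompute from the anchor start: the center index (la//2)
            # is not symmetric under reverse complement for even lengths
            old_start = anchor_center - la // 2
            anchor_center = len(padded) - (old_start + la) + la // 2
        out.append(CenteredRegion(h["region"], padded, anchor_center,
                                  h["strand"], float(h["score"])))
    dropped = len(sequences) - len(out)
    return out, dropped


@dataclass
class SpacingHistogram:
    """Orientation-resolved 1-bp offset frequencies of query around anchor."""

    anchor: str
    query: str
    len_anchor: int
    len_query: int
    n_regions: int
    table: pd.DataFrame  # columns: offset, same_count, opposite_count,
    #                               same_freq, opposite_freq

    def channel(self, orientation: str) -> pd.Series:
        col = "same_count" if orientation == "same" else "opposite_count"
        return self.table.set_index("offset")[col]


def spacing_histogram(
    centered: list[CenteredRegion],
    query: Pwm,
    anchor_len: int,
    bin_size: int = 1,
    threshold: float | None = None,
    anchor_name: str = "anchor",
) -> SpacingHistogram:
    """Offset histogram of query hits around the anchor center.

    Offset = query hit center - anchor center in the oriented frame
    (positive = 3' of the anchor); hits are accumulated separately by
    query orientation relative to the anchor. Frequencies are counts
    divided by the number of contributing regions.
    """
    if bin_size != 1:
        raise NotImplementedError("only 1-bp bins are supported")
    lq = len(query)
    seqs = {c.region: c.seq for c in centered}
    hits = scan(seqs, query, threshold)
    centers = {c.region: c.anchor_center for c in centered}
    window = max((len(c.seq) for c in centered), default=0)
    half = window // 2
    offsets = np.arange(-half, half + 1)
    same = np.zeros(len(offsets), dtype=int)
    oppo = np.zeros(len(offsets), dtype=int)
    for _, h in hits.iterrows():
        off = int(h["start"]) + lq // 2 - centers[h["region"]]
        i = off + half
        if 0 <= i < len(offsets):
            (same if h["strand"] == "+" else oppo)[i] += 1
    n = len(centered)
    table = pd.DataFrame({
        "offset": offsets,
        "same_count": same,
        "opposite_count": oppo,
        "same_freq": same / n if n else 0.0,
        "opposite_freq": oppo / n if n else 0.0,
    })
    return SpacingHistogram(anchor_name, query.name, anchor_len, lq, n, table)


def edge_gap(offset: int, len_anchor: int, len_query: int) -> int:
    """Unoccupied bp between anchor and query implied by a center offset.

    Positive offsets place the query 3' of the anchor: the gap is from
    anchor 3' end to query 5' start; negative offsets mirror this. A
    negative return value means the motif windows physically overlap.
    """
    q_start = len_anchor // 2 + offset - len_query // 2
    q_end = q_start + len_query
    if offset >= 0:
        return q_start - len_anchor
    return -q_end


def spike_offset_for_gap(gap: int, len_anchor: int, len_query: int) -> int:
    """Center offset at which a query planted `gap` bp 3' of the anchor lands."""
    return (len_anchor - len_anchor // 2) + gap + len_query // 2


def detect_spike(
    hist: SpacingHistogram,
    z_min: float = 6.0,
    exclude_overlap: bool = False,
) -> pd.DataFrame:
    """Robustly detect offsets with outlying query-hit counts.

    A spike is an offset whose count exceeds median + z_min * robust
    scale (1.4826 * MAD; unit floor when the MAD is zero), per
    orientation channel. Offsets where the query and anchor windows
    physically overlap (|offset| < (len_anchor + len_query) / 2) are
    annotated as overlap artifacts — e.g. shared subsequences between
    the two motifs — and removed when `exclude_overlap` is set.
    """
    rows = []
    overlap_span = (hist.len_anchor + hist.len_query) / 2
    for orient, col in (("same", "same_count"), ("opposite", "opposite_count")):
        counts = hist.table[col].to_numpy(dtype=float)
        med = np.median(counts)
        mad = np.median(np.abs(counts - med))
        scale = 1.4826 * mad
        if scale == 0:
            scale = 1.0
        thr = med + z_min * scale
        for i in np.flatnonzero(counts > thr):
            off = int(hist.table["offset"].iat[i])
            rows.append({
                "offset": off,
                "orientation": orient,
                "count": int(counts[i]),
                "zscore": (counts[i] - med) / scale,
                "gap": edge_gap(off, hist.len_anchor, hist.len_query),
                "overlap_artifact": abs(off) < overlap_span,
            })
    out = pd.DataFrame(rows, columns=["offset", "orientation", "count",
                                      "zscore", "gap", "overlap_artifact"])
    if exclude_overlap and len(out):
        out = out[~out["overlap_artifact"]].reset_index(drop=True)
    return out.sort_values("count", ascending=False).reset_index(drop=True)


@dataclass
class PairedMotifModel:
    """Combined PWM of an anchor and a precisely spaced query half-site."""

    anchor: Pwm
    query: Pwm
    gap_bp: int
    same_orientation: bool
    combined: Pwm
    n_support: int


def build_paired_model(
    centered: list[CenteredRegion],
    anchor: Pwm,
    query: Pwm,
    offset: int,
    same_orientation: bool = True,
    threshold: float | None = None,
    min_support: int = 20,
    pseudocount: float = 0.5,
    name: str | None = None,
) -> PairedMotifModel:
    """Stack sequences under a detected spacing spike into a combined PWM.

    From each centered region with a query hit at exactly `offset` in
    the requested orientation, the span from anchor 5' start to query
    3' end is extracted in anchor orientation; base counts per column
    (with a pseudocount) give the combined position-probability matrix.
    """
    la, lq = len(anchor), len(query)
    gap = edge_gap(offset, la, lq)
    if gap < 0:
        raise ValueError("cannot build a paired model across overlapping sites")
    want_strand = "+" if same_orientation else "-"
    seqs = {c.region: c.seq for c in centered}
    hits = scan(seqs, query, threshold)
    centers = {c.region: c.anchor_center for c in centered}
    stack = []
    for _, h in hits.iterrows():
        if h["strand"] != want_strand:
            continue
        if int(h["start"]) + lq // 2 - centers[h["region"]] != offset:
            continue
        a_start = centers[h["region"]] - la // 2
        span = seqs[h["region"]][a_start : a_start + la + gap + lq]
        if len(span) == la + gap + lq and "N" not in span:
            stack.append(span)
    if len(stack) < min_support:
        raise ValueError(
            f"insufficient support: {len(stack)} contributing regions < {min_support}"
        )
    counts = np.full((la + gap + lq, 4), pseudocount)
    for span in stack:
        for i, b in enumerate(span):
            counts[i, _CODE[b]] += 1
    matrix = counts / counts.sum(axis=1, keepdims=True)
    combined = Pwm(name or f"{anchor.name}:{query.name}", matrix,
                   anchor.background.copy())
    return PairedMotifModel(anchor, query, gap, same_orientation, combined,
                            len(stack))


def count_instances(
    genome: dict[str, str], pwm: Pwm, threshold: float | None = None
) -> tuple[int, pd.DataFrame]:
    """Greedy non-overlapping best-hit count of a motif genome-wide.

    Hits on both strands above threshold are selected best-score-first,
    discarding any hit overlapping an already selected one; returns the
    instance count and a BED-like frame of kept hits.
    """
    hits = scan(genome, pwm, threshold)
    kept_rows = []
    L = len(pwm)
    for chrom, sub in hits.groupby("region", sort=False):
        taken: list[tuple[int, int]] = []
        for _, h in sub.sort_values(["score", "start"],
                                    ascending=[False, True]).iterrows():
            s = int(h["start"])
            if any(s < e and s + L > b for b, e in taken):
                continue
            taken.append((s, s + L))
            kept_rows.append((chrom, s, s + L, pwm.name, float(h["score"]),
                              h["strand"]))
    bed = pd.DataFrame(kept_rows, columns=["chrom", "start", "end", "name",
                                           "score", "strand"])
    bed = bed.sort_values(["chrom", "start"]).reset_index(drop=True)
    return len(bed), bed
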