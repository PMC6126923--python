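"""Seeded synthetic study inputs with the structure the pipeline assumes.

Generators for genomes (with CpG-island segments), beta-binomial
methylomes with planted hypomethylated and differentially methylated
blocks, TSS/gene annotations with jittered replicate peak sets,
expression tables with planted endothelial-enriched and tissue-specific
genes, and motif-pair-embedded region sequences with exact gap and
orientation control. Every generator is a pure function of its spec,
including the seed, and emits a truth table sufficient to score the
corresponding caller.

Default study conditions mirror the emulated system: background CG
methylation mean 0.67, unmethylated regions at mean mCG 0.10 on CG-rich
islands, low-methylated regions at 0.15 in CG-poor background, depth
~10 reads per CpG, two replicates per subtype, four subtypes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylome import MethylomeTrack
from .motifs import Pwm, revcomp

# Synthetic half-site consensus sequences for the paired-element
# analyses. The ETS-like site begins with AGG and the ZIC-like site ends
# with AGG, reproducing the partial-overlap frequency-spike artifact the
# spacing analysis must annotate.
ETS_CONSENSUS = "AGGAAGTG"
ZIC_CONSENSUS = "CCAGCAGG"

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeSpec:
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    gc_background: float = 0.42
    cpg_island_rate: float = 10.0       # islands per Mb (ignored when
    island_intervals: list | None = None  # explicit intervals are given)
    island_length: int = 1500
    island_gc: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise ValueError("n_chroms and chrom_length must be positive")
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must be in (0, 1)")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def cpg_positions(seq: str) -> np.ndarray:
    """0-based plus-strand C positions of every CG dinucleotide."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr[:-1] == ord("C")
    is_g = arr[1:] == ord("G")
    return np.flatnonzero(is_c & is_g)


def generate_genome(spec: GenomeSpec) -> tuple[dict[str, str], pd.DataFrame,
                                               pd.DataFrame]:
    """Random genome with CpG-island segments; returns (genome, CpG
    table, island table). Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    island_rows, cpg_rows = [], []
    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        codes = _random_seq(rng, spec.chrom_length, spec.gc_background)
        if spec.island_intervals is not None:
            islands = [(c, s, e) for c, s, e in spec.island_intervals
                       if c == chrom]
        else:
            n_isl = rng.poisson(spec.cpg_island_rate * spec.chrom_length / 1e6)
            starts = np.sort(rng.integers(
                0, max(1, spec.chrom_length - spec.island_length), size=n_isl))
            islands = [(chrom, int(s), int(s) + spec.island_length)
                       for s in starts]
        for c, s, e in islands:
            if s < 0 or e > spec.chrom_length:
                raise ValueError(f"island {c}:{s}-{e} outside chromosome")
            codes[s:e] = _random_seq(rng, e - s, spec.island_gc)
            island_rows.append((c, s, e))
        seq = "".join(_BASES[codes])
        genome[chrom] = seq
        for pos in cpg_positions(seq):
            cpg_rows.append((chrom, int(pos)))
    cpgs = pd.DataFrame(cpg_rows, columns=["chrom", "pos"])
    islands_df = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    return genome, cpgs, islands_df


@dataclass
class MethylomeSpec:
    background_mean_mcg: float = 0.67
    background_dispersion: float = 20.0   # Beta concentration, background CpGs
    feature_dispersion: float = 100.0     # Beta concentration inside planted
    #   features: hypomethylated regions are coherently unmethylated, so the
    #   per-CpG latent fraction varies far less than in partially methylated
    #   background
    umr_targets: list = field(default_factory=list)  # (chrom, start, end, mcg)
    lmr_targets: list = field(default_factory=list)
    dmr_targets: list = field(default_factory=list)  # (chrom, start, end,
    #                                                   {sample: mcg})
    depth_mean: float = 10.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for group in (self.umr_targets, self.lmr_targets):
            for c, s, e, m in group:
                if not 0 <= m <= 1:
                    raise ValueError(f"target mCG {m} outside [0, 1]")
        for c, s, e, mapping in self.dmr_targets:
            for m in mapping.values():
                if not 0 <= m <= 1:
                    raise ValueError(f"target mCG {m} outside [0, 1]")


def _check_bounds(targets, chrom_lengths: dict[str, int]) -> None:
    for t in targets:
        c, s, e = t[0], t[1], t[2]
        if c not in chrom_lengths or s < 0 or e > chrom_lengths[c] or s >= e:
            raise ValueError(f"planted interval {c}:{s}-{e} outside genome")


def generate_methylome(
    cpgs: pd.DataFrame,
    spec: MethylomeSpec,
    sample: str = "s1",
    chrom_lengths: dict[str, int] | None = None,
) -> list[MethylomeTrack]:
    """One beta-binomial methylome track per replicate for one sample.

    Each CpG's latent methylation fraction is Beta-distributed around
    the locally applicable target mean (background, or a planted UMR /
    LMR / DMR block), redrawn per replicate; coverage is Poisson at
    depth_mean and methylated counts binomial.
    """
    if chrom_lengths is not None:
        _check_bounds(spec.umr_targets, chrom_lengths)
        _check_bounds(spec.lmr_targets, chrom_lengths)
        _check_bounds(spec.dmr_targets, chrom_lengths)
    # per-CpG target mean, by precedence: DMR (sample-specific) > UMR/LMR
    target = np.full(len(cpgs), spec.background_mean_mcg)
    conc = np.full(len(cpgs), spec.background_dispersion)
    chrom_arr = cpgs["chrom"].to_numpy()
    pos_arr = cpgs["pos"].to_numpy()
    for c, s, e, m in list(spec.umr_targets) + list(spec.lmr_targets):
        sel = (chrom_arr == c) & (pos_arr >= s) & (pos_arr < e)
        target[sel] = m
        conc[sel] = spec.feature_dispersion
    for c, s, e, mapping in spec.dmr_targets:
        sel = (chrom_arr == c) & (pos_arr >= s) & (pos_arr < e)
        conc[sel] = spec.feature_dispersion
        if sample in mapping:
            target[sel] = mapping[sample]
    tracks = []
    for rep in range(spec.n_replicates):
        rng = np.random.default_rng(
            [spec.seed, zlib.crc32(sample.encode()) % (2**31), rep])
        a = np.clip(target * conc, 1e-3, None)
        b = np.clip((1 - target) * conc, 1e-3, None)
        p = rng.beta(a, b)
        cov = rng.poisson(spec.depth_mean, size=len(cpgs))
        mc = rng.binomial(cov, p)
        sites = pd.DataFrame({
            "chrom": chrom_arr, "pos": pos_arr, "mc": mc, "cov": cov,
        })
        tracks.append(MethylomeTrack(sites, sample=sample,
                                     replicate=f"rep{rep + 1}"))
    return tracks


def place_intervals(
    rng: np.random.Generator,
    chrom: str,
    chrom_length: int,
    lengths: list[int],
    min_sep: int = 2000,
    occupied: list[tuple[int, int]] | None = None,
) -> list[tuple[str, int, int]]:
    """Place non-overlapping intervals of given lengths, min_sep apart."""
    taken = list(occupied or [])
    out = []
    for L in lengths:
        for _ in range(10_000):
            s = int(rng.integers(0, chrom_length - L))
            e = s + L
            if all(s - min_sep >= te or e + min_sep <= ts for ts, te in taken):
                taken.append((s, e))
                out.append((chrom, s, e))
                break
        else:
            raise ValueError("could not place intervals; genome too small")
    return out


@dataclass
class MotifEmbeddingSpec:
    anchor_pwm: Pwm
    query_pwm: Pwm
    gap_bp: int = 2
    same_orientation: bool = True
    n_regions: int = 100
    region_length: int = 1000
    embed_fraction: float = 1.0
    gc: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        span = len(self.anchor_pwm) + max(0, self.gap_bp) + len(self.query_pwm)
        if self.region_length < span:
            raise ValueError("region_length smaller than combined motif span")
        if not 0 <= self.embed_fraction <= 1:
            raise ValueError("embed_fraction must be in [0, 1]")


def embed_motif_pairs(
    spec: MotifEmbeddingSpec,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random regions with anchor+query consensus pairs at an exact gap.

    In ``embed_fraction`` of regions the anchor consensus is written on
    the plus strand and the query consensus ``gap_bp`` unoccupied bp 3'
    of the anchor end, on the same or opposite strand. Returns the
    region sequences and a truth table of planted coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    a_cons = spec.anchor_pwm.consensus
    q_cons = spec.query_pwm.consensus
    la, lq = len(a_cons), len(q_cons)
    span = la + spec.gap_bp + lq
    n_embed = int(round(spec.embed_fraction * spec.n_regions))
    seqs, rows = {}, []
    for i in range(spec.n_regions):
        codes = _random_seq(rng, spec.region_length, spec.gc)
        seq = list("".join(_BASES[codes]))
        rid = f"region_{i}"
        if i < n_embed:
            margin = spec.region_length - span
            if margin < 0:
                raise ValueError("gap pushes query outside region")
            a_start = int(rng.integers(0, margin + 1))
            q_start = a_start + la + spec.gap_bp
            seq[a_start : a_start + la] = a_cons
            q_written = q_cons if spec.same_orientation else revcomp(q_cons)
            seq[q_start : q_start + lq] = q_written
            rows.append((rid, a_start, q_start, spec.gap_bp,
                         "+" if spec.same_orientation else "-"))
        seqs[rid] = "".join(seq)
    truth = pd.DataFrame(rows, columns=["region", "anchor_start",
                                        "query_start", "gap", "query_strand"])
    return seqs, truth


@dataclass
class ExpressionSpec:
    n_genes: int = 1000
    subtypes: tuple[str, ...] = ("brain", "liver", "lung", "kidney")
    n_replicates: int = 2
    n_ec_enriched: int = 50
    n_ectsg_per_subtype: int = 10
    n_non_ec: int = 30              # planted parenchymal (GFP-negative) genes
    fold_effect: float = 4.0
    noncoding_fraction: float = 0.1
    tpm_logmean: float = 2.0        # log-normal baseline TPM parameters
    tpm_logsd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_effect <= 1:
            raise ValueError("fold_effect must exceed 1")
        need = self.n_ec_enriched + self.n_non_ec
        if need > self.n_genes:
            raise ValueError("planted sets exceed n_genes")
        if self.n_ectsg_per_subtype * len(self.subtypes) > self.n_ec_enriched:
            raise ValueError("planted ECTSGs exceed planted EC-enriched genes")


def generate_expression_table(
    spec: ExpressionSpec,
) -> tuple[pd.DataFrame, dict]:
    """Expression table with planted EC-enriched / ECTSG / parenchymal genes.

    Fold and PPDE columns are written directly (they are model outputs
    consumed by the filter cascade), so planted genes satisfy the
    filter criteria by construction and every non-planted gene violates
    at least one criterion. Returns (table, truth) where truth maps
    ``ec_enriched`` to the planted gene set, ``ectsg`` to the
    per-subtype planted sets, and ``non_ec`` to the parenchymal set.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    subtypes = list(spec.subtypes)
    ec_set = set(genes[: spec.n_ec_enriched])
    ectsg: dict[str, set[str]] = {}
    cursor = 0
    for s in subtypes:
        ectsg[s] = set(genes[cursor : cursor + spec.n_ectsg_per_subtype])
        cursor += spec.n_ectsg_per_subtype
    non_ec = set(genes[spec.n_ec_enriched : spec.n_ec_enriched + spec.n_non_ec])

    n = spec.n_genes
    biotype = np.where(rng.random(n) < spec.noncoding_fraction,
                       "non_coding", "protein_coding")
    base = np.exp(rng.normal(spec.tpm_logmean, spec.tpm_logsd, size=n))
    table = pd.DataFrame({"gene": genes, "biotype": biotype})
    is_ec = np.isin(genes, list(ec_set))
    is_non_ec = np.isin(genes, list(non_ec))

    for s in subtypes:
        is_ts = np.isin(genes, list(ectsg[s]))
        in_other_ts = np.zeros(n, dtype=bool)
        for o in subtypes:
            if o != s:
                in_other_ts |= np.isin(genes, list(ectsg[o]))
        # GFP-positive TPM: planted EC genes comfortably above min_tpm;
        # tissue-specific genes depressed in the other tissues
        pos_base = np.where(is_ec, np.maximum(base, 15.0), base)
        pos_base = np.where(in_other_ts, pos_base / spec.fold_effect, pos_base)
        for rep in range(1, spec.n_replicates + 1):
            noise = rng.lognormal(0, 0.05, size=n)
            table[f"tpm_{s}_pos_{rep}"] = pos_base * noise
            table[f"tpm_{s}_neg_{rep}"] = np.where(
                is_non_ec, pos_base * spec.fold_effect,
                pos_base / spec.fold_effect) * rng.lognormal(0, 0.05, size=n)
        # GFP+/- fold and PPDE: planted EC genes pass, others fail at
        # least one criterion (randomly fold, PPDE, or TPM — TPM failures
        # arise from base < 10 which the fold/PPDE draws don't rescue)
        fail_mode = rng.integers(0, 3, size=n)
        fold = np.where(is_ec, spec.fold_effect * rng.uniform(1.0, 1.5, n),
                        np.where(fail_mode == 0, rng.uniform(0.2, 1.9, n),
                                 rng.uniform(2.0, 6.0, n)))
        ppde = np.where(is_ec, rng.uniform(0.97, 1.0, n),
                        np.where(fail_mode == 1, rng.uniform(0.0, 0.9, n),
                                 rng.uniform(0.96, 1.0, n)))
        # remaining failure mode: force sub-threshold TPM in replicate 1
        force_low = (~is_ec) & (fail_mode == 2)
        col = f"tpm_{s}_pos_1"
        table.loc[force_low, col] = rng.uniform(0.1, 9.0, force_low.sum())
        table[f"fold_pos_neg_{s}"] = fold
        table[f"ppde_pos_neg_{s}"] = ppde
        table[f"fold_neg_pos_{s}"] = np.where(
            is_non_ec, spec.fold_effect * rng.uniform(1.0, 1.5, n),
            rng.uniform(0.1, 1.9, n))

    for s in subtypes:
        is_ts = np.isin(genes, list(ectsg[s]))
        for o in subtypes:
            if o == s:
                continue
            fold_so = np.where(
                is_ts, spec.fold_effect * rng.uniform(1.0, 1.5, n),
                rng.uniform(0.3, 1.9, n))
            table[f"fold_{s}_vs_{o}"] = fold_so
            table[f"ppde_{s}_vs_{o}"] = np.where(
                is_ts, rng.uniform(0.97, 1.0, n), rng.uniform(0.5, 1.0, n))
    # make pairwise folds mutually consistent where a planted call exists
    for s in subtypes:
        for o in subtypes:
            if o == s:
                continue
            is_ts_o = np.isin(genes, list(ectsg[o]))
            table.loc[is_ts_o, f"fold_{s}_vs_{o}"] = \
                1.0 / table.loc[is_ts_o, f"fold_{o}_vs_{s}"]
    truth = {"ec_enriched": ec_set, "ectsg": ectsg, "non_ec": non_ec}
    return table, truth


def segmentation_study(seed: int = 1, chrom_length: int = 4_000_000) -> dict:
    """Canonical segmentation-recovery study.

    4 Mb single-chromosome genome; 50 CG-rich unmethylated blocks at
    target mCG 0.10 on CpG islands (40 of 1.5-2.5 kb, 10 valley-sized
    at 3.5-4.5 kb), 200 CG-poor low-methylated blocks at 0.15 and
    400-520 bp (~17-22 CpGs, below the 30-CpG UMR class boundary),
    background 0.67, depth 10. Returns genome, CpG table, one methylome
    track, and truth tables.
    """
    rng = np.random.default_rng(seed)
    umr_lens = [int(rng.integers(1500, 2500)) for _ in range(40)] + \
               [int(rng.integers(3500, 4500)) for _ in range(10)]
    lmr_lens = [int(rng.integers(400, 520)) for _ in range(200)]
    placed = place_intervals(rng, "chr1", chrom_length, umr_lens + lmr_lens,
                             min_sep=2500)
    umr_iv, lmr_iv = placed[:50], placed[50:]
    genome, cpgs, _ = generate_genome(GenomeSpec(
        chrom_length=chrom_length, island_intervals=list(umr_iv), seed=seed))
    spec = MethylomeSpec(
        umr_targets=[(c, s, e, 0.10) for c, s, e in umr_iv],
        lmr_targets=[(c, s, e, 0.15) for c, s, e in lmr_iv],
        depth_mean=10, n_replicates=1, seed=seed)
    track = generate_methylome(cpgs, spec, sample="ec",
                               chrom_lengths={c: len(s)
                                              for c, s in genome.items()})[0]
    umr_truth = pd.DataFrame(umr_iv, columns=["chrom", "start", "end"])
    lmr_truth = pd.DataFrame(lmr_iv, columns=["chrom", "start", "end"])
    return {"genome": genome, "cpgs": cpgs, "track": track,
            "umr_truth": umr_truth, "lmr_truth": lmr_truth,
            "dmv_truth": umr_truth[umr_truth["end"] - umr_truth["start"]
                                   > 3000].reset_index(drop=True)}


def dmr_study(seed: int = 1, chrom_length: int = 1_000_000,
              n_blocks: int = 30, delta: float = 0.4,
              depth: float = 10.0, n_replicates: int = 2) -> dict:
    """Two-subtype differential-methylation study with planted blocks.

    Plants ``n_blocks`` 1-kb blocks where subtype A drops by `delta`
    below the 0.67 background (subtype B stays at background); both
    subtypes have `n_replicates` replicate tracks at `depth`. Returns
    replicate and pooled tracks plus the truth intervals.
    """
    rng = np.random.default_rng(seed)
    blocks = place_intervals(rng, "chr1", chrom_length, [1000] * n_blocks,
                             min_sep=3000)
    # planted blocks sit on CpG-enriched segments, as candidate CREs do
    # relative to depleted genomic background
    genome, cpgs, _ = generate_genome(GenomeSpec(
        chrom_length=chrom_length, island_intervals=list(blocks), seed=seed))
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    dmr_targets = [(c, s, e, {"A": 0.67 - delta}) for c, s, e in blocks]
    replicate_tracks = {}
    for sample in ("A", "B"):
        spec = MethylomeSpec(dmr_targets=dmr_targets, depth_mean=depth,
                             n_replicates=n_replicates, seed=seed)
        replicate_tracks[sample] = generate_methylome(
            cpgs, spec, sample=sample, chrom_lengths=chrom_lengths)
    pooled = {}
    for sample, reps in replicate_tracks.items():
        merged = (pd.concat([t.sites for t in reps])
                  .groupby(["chrom", "pos"], as_index=False)[["mc", "cov"]]
                  .sum().sort_values(["chrom", "pos"]).reset_index(drop=True))
        pooled[sample] = MethylomeTrack(merged, sample=sample,
                                        replicate="pooled")
    truth = pd.DataFrame(blocks, columns=["chrom", "start", "end"])
    return {"cpgs": cpgs, "replicate_tracks": replicate_tracks,
            "pooled": pooled, "truth": truth}


def generate_annotation(
    genome: dict[str, str],
    n_genes: int,
    seed: int = 0,
    gene_length: tuple[int, int] = (2000, 10000),
    n_peaks: int = 50,
    n_replicates: int = 2,
    peak_length: tuple[int, int] = (200, 600),
    jitter: int = 0,
) -> dict:
    """Gene bodies, TSSs, and jittered replicate peak sets.

    Genes are non-overlapping with random strand; the TSS is the gene
    start on plus-strand genes and the last covered base (end - 1, BED
    half-open) on minus-strand genes. Replicate peak sets are copies of
    a shared truth set with uniform +-jitter on both edges.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    total = sum(len(genome[c]) for c in chroms)
    if total < n_genes * (gene_length[1] + 1000):
        raise ValueError("genome too small for requested gene count")
    gene_rows, tss_rows = [], []
    per_chrom = int(np.ceil(n_genes / len(chroms)))
    gi = 0
    for chrom in chroms:
        lens = rng.integers(gene_length[0], gene_length[1] + 1,
                            size=per_chrom)
        placed = place_intervals(rng, chrom, len(genome[chrom]),
                                 [int(x) for x in lens], min_sep=500)
        for (c, s, e) in placed:
            if gi >= n_genes:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"gene_{gi:05d}"
            gene_rows.append((c, s, e, name, 0, strand))
            tss = s if strand == "+" else e - 1
            tss_rows.append((c, tss, strand, name))
            gi += 1
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end",
                                             "name", "score", "strand"])
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "name"])

    occupied = [(s, e) for _, s, e in
                ((r[0], r[1], r[2]) for r in gene_rows)]
    peak_lens = rng.integers(peak_length[0], peak_length[1] + 1, size=n_peaks)
    chrom0 = chroms[0]
    truth_peaks = pd.DataFrame(
        place_intervals(rng, chrom0, len(genome[chrom0]),
                        [int(x) for x in peak_lens], min_sep=1000),
        columns=["chrom", "start", "end"])
    replicates = []
    for rep in range(n_replicates):
        r = truth_peaks.copy()
        if jitter > 0:
            r["start"] = np.maximum(
                0, r["start"] + rng.integers(-jitter, jitter + 1, len(r)))
            r["end"] = np.maximum(
                r["start"] + 1,
                r["end"] + rng.integers(-jitter, jitter + 1, len(r)))
        replicates.append(r)
    return {"genes": genes, "tss": tss, "truth_peaks": truth_peaks,
            "replicate_peaks": replicates}
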