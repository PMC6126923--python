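# Methods

This note documents the models, parameter defaults, and numerical
choices behind each stage of the pipeline, and what the synthetic-data
module does and does not emulate.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention); abutting
intervals never overlap. Methylation tables are allc-style TSV
(chrom, pos, strand, context, methylated count, total count); the
reader can pool strand-symmetric CG calls onto the plus-strand C, and
all downstream code assumes pooled plus-strand records. Motif models
are HOMER-style text (`>consensus name threshold` followed by
per-position probability rows). All writers gzip transparently when a
path ends in `.gz`.

## Methylome segmentation

A methylome track is an ordered list of per-CpG (methylated, total)
read counts. The smoothed methylation value at CpG *i* is the
count-sum fraction (Σ mc)/(Σ cov) over a window of `window_cpgs` CpGs
centered at *i* (truncated at chromosome ends; zero-coverage windows
are missing). Smoothing by CpG index rather than by bp makes the
estimator robust to CpG-density variation.

Hypomethylated regions are maximal runs of at least `min_cpgs` = 4
consecutive CpGs whose smoothed value is strictly below *m* = 0.3;
the reported interval spans the first to last member CpG (end
exclusive at last CpG + 1), and the attached mean mCG is the raw
coverage-weighted fraction. Regions with ≥ 30 CpGs are UMRs, the rest
LMRs — a fixed count split rather than a data-driven density cut,
chosen for determinism and testability. UMRs strictly longer than
3000 bp are DMVs.

**Smoothing window default (7 CpGs).** The window size sets the
trade-off between boundary resolution and run-breaking noise. At the
coverage this package targets (≈ 10 reads per CpG), a window of
3 CpGs aggregates only ~30 reads, and for a region with true
methylation 0.10–0.15 the probability that a single window crosses
*m* = 0.3 by sampling noise alone is 0.2–1.5% per window — enough to
split a feature with 50–200 CpGs into fragments in a large fraction of
cases. A 7-CpG window (~70 reads) pushes that probability below 10⁻³
while costing only ~3 CpGs of boundary trim per side, so 7 is the
default; deeply sequenced data can use smaller windows via
`SegmentationParams.window_cpgs`.

An operating-point check is available via within-chromosome shuffling
of (mc, cov) pairs: the achieved FDR is the mean shuffled region count
divided by the real count. It is reported, never used to auto-tune.

## Differential hypomethylation

At each CpG covered in ≥ 2 samples, the statistic is the
root-mean-square deviation of per-sample methylated fractions from the
pooled fraction. Its p-value is the add-one Monte-Carlo upper tail
from `num_sims` = 3000 parametric draws of Binomial(covₛ, pooled rate)
per sample; all draws are always used (no sequential stopping), so the
Monte-Carlo error is uniform across sites. As a pure optimization,
sites whose chi-square homogeneity p-value exceeds 0.2 (20× any useful
cutoff, and chi-square is anti-conservative at small counts, so the
screen only retains extra sites) skip the simulation; `screen_alpha=None`
disables this.

Samples are subtype-pooled tracks (replicates combined), which at
~10× per-replicate depth supplies the counting depth the site test
needs; replicate evidence is enforced afterwards at region level.
Significant sites (p < 0.01) within 250 bp chain into candidate DMRs.
A chain must contain at least `min_dms` = 4 significant CpGs: at
shallow coverage ~1% of null sites are significant by chance and a
singleton chain would trivially pass the mean-difference filter over
its one-site interval; requiring 4 chained, direction-consistent CpGs
drives the null DMR rate to ~0 per 10⁵ CpGs while 1-kb planted blocks
carry ~30 significant sites. A sample enters a DMR's hypo set when
its interval mean mCG is ≥ `min_diff` = 0.3 below the mean of the
other samples and its site residuals are negative at a majority of
member sites; `min_diff` is exposed in config because the emulated
analysis does not print its value. Replicate support then requires
every replicate of a candidate subtype to individually satisfy the
mean-difference rule over the interval (subtypes with a single
replicate are retained with a warning).

ECTS-hypo-DMRs are DMRs whose hypo set is exactly one subtype. Large
hypo-DMRs union ECTS-hypo-DMRs across gaps ≤ 1000 bp and keep merged
intervals strictly longer than 2000 bp.

Site p-values are used at the cutoff without genome-wide correction
(mirroring the printed parameterization of the emulated analysis); a
Benjamini–Hochberg helper is available for enrichment tables.

## Expression filters

Fold changes and PPDE (posterior probability of differential
expression; 1 − FDR) are consumed as inputs, as produced by an
empirical-Bayes differential-expression model; this package does not
refit them. A pseudocount fold of replicate-mean TPMs,
(mean + 1)/(mean + 1), is available as a clearly labeled
non-equivalent fallback. All thresholds are closed (≥ 2-fold,
PPDE ≥ 0.95, TPM ≥ 10) except the GFP-negative exclusion list's
strict > 2. The between-subtype criterion is applied to the supplied
pair statistics for every other subtype, so tissue-specific sets are
disjoint by construction (asserted, not assumed). The nesting
ECTSG(S) ⊆ differential(S) ⊆ EC-enriched is checked on every cascade
run.

## Interval statistics

Overlap is ≥ 1 bp of shared half-open extent everywhere ("intersect
-u" semantics); "shared" and "specific" are overlap-based, not
reciprocal-fraction based. Nearest-TSS distance is unsigned (0 when
the feature contains the TSS; gap from the nearest covered base
otherwise), with strand entering only through TSS placement (gene
start on plus, last covered base on minus). Consensus peaks union all
replicate peaks (overlapping or abutting coalesce) and keep merged
regions containing peaks from ≥ ceil(frac × R) distinct replicates —
with frac = 0.66 the 2-of-2 / 2-of-3 rule; the reference tool's
internal behavior is not reproduced bit-for-bit. Fragment filtering
keeps insert lengths strictly below 100 bp (nucleosome-free range).
The enrichment statistic is the exact hypergeometric upper tail
P(X ≥ k) with all four counting arguments explicit
(scipy's implementation, log-space internally); recovery scoring uses
≥ 50% reciprocal overlap in both directions.

## Motif toolkit

PWMs score as log₂-odds against a background distribution; N scores 0.
The default hit threshold is 0.8 × the maximal attainable score per
motif (database per-motif thresholds are not available). Scanning
covers both strands; minus-strand hits are reported at the plus-strand
start of the occupied window. Best hits break ties by leftmost
position, then plus strand.

GC-matched backgrounds draw, per target, `ratio` = 2 regions of
identical length uniformly from the genome, accepted when their GC
falls in the same 0.05-wide bin and they overlap no target; after 200
rejections the bin relaxes to adjacent bins (tallied). Known-motif
enrichment is region-presence based: fold = %targets-with-motif /
%background-with-motif, p exact hypergeometric, q Benjamini–Hochberg
across motifs, significant iff q < 0.001 and fold > 2 (both strict).
The k-mer table (canonicalized over strands, presence-counted, exact
p) is the deliberately simplified stand-in for de novo motif
discovery; it ranks planted k-mers first but performs no
expectation-maximization refinement.

Spacing analysis centers each region on its best anchor hit, orients
it so the anchor reads on the plus strand, and accumulates query-hit
center offsets (positive = 3′ of the anchor) in 1-bp bins per relative
orientation; frequencies are counts / contributing regions. Offsets
are center-to-center with integer centers at start + length//2; the
derived half-site gap (unoccupied bp between anchor 3′ end and query
5′ start) is reported alongside so either convention can be read off.
Spikes are offsets whose count exceeds median + 6 × robust scale
(1.4826 × MAD, unit floor when the MAD is zero) per channel. Offsets
with |offset| < (len_anchor + len_query)/2 place the two motif windows
on overlapping sequence and are annotated as overlap artifacts — the
class produced when the query motif shares a subsequence with the
anchor (here, the ZIC motif's terminal AGG matching the ETS motif's
initial AGG) — and are excluded from reported spacings on request.
The combined paired model stacks the anchor-start → query-end spans of
all regions with a query hit at the chosen offset and orientation
(≥ 20 required) into a position-probability matrix with pseudocount
0.5; gap columns then carry near-background probabilities. Genome-wide
instance counting selects hits greedily best-score-first, discarding
overlaps.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its spec including the seed, and
emits truth tables sufficient to score recall and precision of every
downstream caller.

- **Genome**: i.i.d. nucleotides at the requested GC (default 0.42)
  with explicit CpG-island segments at elevated GC (0.60). The CpG
  depletion of real mammalian background (~5× below expectation) is
  not modelled, so background CpG spacing (~23 bp) is denser than in a
  real genome; feature CpG counts, not genomic spacing realism, are
  what the downstream statistics consume. Planted hypo-DMR blocks sit
  on CpG-enriched segments, as candidate CREs do relative to depleted
  background.
- **Methylomes**: per-CpG latent methylation drawn from a Beta
  centered on the locally applicable target (background 0.67,
  concentration 20; planted features concentration 100 — a
  hypomethylated regulatory region is coherently unmethylated, so its
  per-CpG latent variance is far smaller than partially methylated
  background), coverage Poisson (default mean 10), methylated counts
  binomial. Replicates share the planted structure and redraw the
  noise. Bisulfite conversion error, mapping bias, and CH-context
  methylation are not modelled.
- **Study conditions** (the canonical recovery fixtures): 50 CG-rich
  blocks at mCG 0.10 (40 of 1.5–2.5 kb, 10 valley-sized at 3.5–4.5 kb)
  and 200 CG-poor blocks at 0.15 and 400–520 bp (~17–22 CpGs, safely
  below the 30-CpG class boundary and near the enhancer-scale median
  length the package targets), background 0.67, depth 10, on a 4 Mb
  chromosome; differential-methylation fixtures plant 1-kb blocks with
  Δ mCG 0.4 at two replicates per subtype. Problem sizes (2–4 Mb
  genomes, 10⁵–10⁶ CpGs per comparison) were chosen so each stage's
  statistics are well-resolved at desk scale.
- **Expression tables**: fold/PPDE columns are written directly so
  planted genes satisfy the cascade by construction and every
  non-planted gene violates at least one criterion (randomly fold,
  PPDE, or TPM); pairwise folds are made mutually consistent. TPMs
  echo the folds with log-normal noise but are not generated from a
  count model.
- **Motif regions**: anchor and query consensus strings written with
  an exact unoccupied gap, query on either strand; truth tables record
  every planted coordinate. The synthetic half-sites (`AGGAAGTG`,
  `CCAGCAGG`) reproduce the shared-AGG overlap artifact by
  construction. Real PWM degeneracy (information-content variation
  across positions) is only approximated by the 0.97-certainty
  consensus model.

Passing tests on these fixtures demonstrates that each algorithm
recovers the structure it is designed to find under controlled noise;
they do not certify performance on real bisulfite or ATAC data, where
coverage heterogeneity, partially methylated domains, and repeat
content add failure modes the generator deliberately omits.

## Pipeline orchestration

`run_all` validates a YAML config (unknown keys are errors — silent
parameter typos are the dominant reproducibility hazard in multi-stage
pipelines), executes segmentation → differential methylation → merging
→ expression filters → overlap statistics → motif spacing, and writes
a run manifest (config hash, per-stage output checksums, timings,
aggregated warnings; written atomically). The global seed splits into
per-stage seeds by CRC32 of the stage name, so stage-level
reproducibility is independent of stage order. Outputs are
deterministic per (config, seed); the CLI `run` command short-circuits
to a no-op when the manifest shows the same config hash and all output
checksums still match. Exit codes: 0 ok, 2 config error, 3 stage
failure.

## Known limitations

- The site test's Monte-Carlo p-value floor is 1/(num_sims + 1); with
  genome-wide correction enabled this floor, not the data, can limit
  detection. The default parameterization (raw p at 0.01 with the
  min_dms chain rule) avoids this at the cost of per-site FDR
  guarantees.
- The UMR/LMR split by fixed CpG count misclassifies features whose
  CpG count straddles 30; the emulated analysis may have used a
  density-based cut.
- Spacing offsets use integer centers (start + length//2); for
  even-length motifs the "center" is the left-of-center base, which
  shifts all offsets of a given pair by a constant and cancels in gap
  arithmetic.
- `estimate_segmentation_fdr` destroys local CpG-density structure
  when shuffling, so its null is conservative for density-correlated
  methylation.
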