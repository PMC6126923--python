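"""Differential hypomethylation: RMS site test, DMR chaining, merging.

The site-level statistic is the root-mean-square deviation of per-sample
methylated fractions from the pooled fraction under the homogeneity
null; its p-value is a parametric Monte-Carlo upper tail from
``num_sims`` binomial draws per sample at the pooled rate. Significant
sites within ``dmr_max_dist`` bp of each other are chained into DMRs;
a sample is called hypomethylated for a DMR when its region-level mean
mCG lies at least ``min_diff`` below the mean of the other samples and
its site residuals are negative at a majority of member sites.

Tissue-specific (ECTS) hypo-DMRs are those uniquely hypomethylated in a
single subtype; chains of nearby ECTS-hypo-DMRs merged across gaps of
up to ``merge_gap`` bp that exceed ``large_min_len`` bp form the large
hypo-DMR class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylome import MethylomeTrack


@dataclass
class DmrParams:
    dmr_max_dist: int = 250      # max bp between chained significant sites
    sig_cutoff: float = 0.01     # site-level Monte-Carlo p cutoff
    num_sims: int = 3000         # Monte-Carlo draws per tested site
    min_diff: float = 0.3        # required mCG drop vs rest-of-samples mean
    min_dms: int = 4             # minimum significant sites per DMR; at
    #   shallow (~10-20x) coverage single significant CpGs arise at the
    #   nominal site rate and would otherwise pass the mean-difference
    #   filter trivially over a one-site interval
    merge_gap: int = 1000        # gap merged when building large hypo-DMRs
    large_min_len: int = 2000    # strict length cutoff for large hypo-DMRs

    def __post_init__(self) -> None:
        if self.dmr_max_dist < 0:
            raise ValueError("dmr_max_dist must be >= 0")
        if not 0 < self.sig_cutoff < 1:
            raise ValueError("sig_cutoff must be in (0, 1)")
        if self.num_sims < 100:
            raise ValueError("num_sims must be >= 100")


def rms_statistic(mc: np.ndarray, cov: np.ndarray) -> float:
    """RMS deviation of covered samples' fractions from the pooled fraction."""
    covered = cov > 0
    if covered.sum() < 2:
        raise ValueError("need >= 2 samples with coverage")
    pooled = mc[covered].sum() / cov[covered].sum()
    f = mc[covered] / cov[covered]
    return float(np.sqrt(np.mean((f - pooled) ** 2)))


def rms_site_test(
    mc: np.ndarray,
    cov: np.ndarray,
    num_sims: int = 3000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Monte-Carlo homogeneity test at one CpG site.

    Returns (p, residual_signs). p is the add-one upper-tail estimate
    P(stat* >= stat_obs); residual signs are sign(f_s - pooled) per
    sample (0 for uncovered samples).
    """
    mc = np.asarray(mc, dtype=float)
    cov = np.asarray(cov, dtype=float)
    p_mat, signs = rms_site_tests(mc[None, :], cov[None, :], num_sims, seed)
    return float(p_mat[0]), signs[0]


def rms_site_tests(
    mc: np.ndarray,
    cov: np.ndarray,
    num_sims: int = 3000,
    seed: int = 0,
    chunk: int = 2000,
    screen_alpha: float | None = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Monte-Carlo RMS test over many sites.

    `mc` and `cov` are (n_sites, n_samples) arrays. Sites with fewer
    than two covered samples get p = NaN (skipped). All ``num_sims``
    draws are always used (no sequential stopping), which keeps the
    Monte-Carlo error uniform across sites.

    When `screen_alpha` is set, sites whose chi-square homogeneity
    p-value exceeds it are reported with that (approximate) p and skip
    the simulation. The screen is far above any useful significance
    cutoff and the chi-square approximation is anti-conservative at
    small counts, so every site that could reach significance is still
    simulated exactly. Pass None to simulate every site.
    """
    from scipy.stats import chi2

    mc = np.asarray(mc, dtype=float)
    cov = np.asarray(cov, dtype=float)
    n_sites, n_samples = mc.shape
    rng = np.random.default_rng(seed)
    p = np.full(n_sites, np.nan)
    signs = np.zeros((n_sites, n_samples), dtype=np.int8)
    covered = cov > 0
    testable = covered.sum(axis=1) >= 2
    if not testable.all():
        n_skip = int((~testable).sum())
        if n_skip:
            warnings.warn(f"skipping {n_skip} sites with <2 covered samples",
                          stacklevel=2)
    idx_all = np.flatnonzero(testable)

    if screen_alpha is not None and len(idx_all):
        c = cov[idx_all]
        m = mc[idx_all]
        mask = c > 0
        tot = c.sum(axis=1)
        pooled = m.sum(axis=1) / tot
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(mask, m / np.maximum(c, 1e-300), 0.0)
        denom = pooled * (1 - pooled)
        x2 = np.where(
            denom[:, None] > 0,
            c * (f - pooled[:, None]) ** 2 / np.maximum(denom[:, None], 1e-300),
            0.0,
        )
        x2_stat = np.where(mask, x2, 0.0).sum(axis=1)
        dof = mask.sum(axis=1) - 1
        p_chi2 = chi2.sf(x2_stat, np.maximum(dof, 1))
        signs[idx_all] = np.sign(
            np.where(mask, f - pooled[:, None], 0.0)).astype(np.int8)
        clear = p_chi2 > screen_alpha
        p[idx_all[clear]] = p_chi2[clear]
        idx_all = idx_all[~clear]
    for lo in range(0, len(idx_all), chunk):
        idx = idx_all[lo : lo + chunk]
        c = cov[idx]                       # (b, S)
        m = mc[idx]
        mask = c > 0
        tot = c.sum(axis=1, keepdims=True)
        pooled = m.sum(axis=1, keepdims=True) / tot
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(mask, m / np.maximum(c, 1e-300), 0.0)
        dev = np.where(mask, f - pooled, 0.0)
        k = mask.sum(axis=1)
        stat = np.sqrt((dev**2).sum(axis=1) / k)
        signs[idx] = np.sign(np.where(mask, f - pooled, 0.0)).astype(np.int8)
        # null draws: Binomial(cov_s, pooled) per sample per simulation
        draws = rng.binomial(
            c[:, :, None].astype(np.int64), pooled[:, :, None],
            size=(len(idx), n_samples, num_sims),
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            f_null = np.where(
                mask[:, :, None], draws / np.maximum(c[:, :, None], 1e-300), 0.0
            )
        dev_null = np.where(mask[:, :, None], f_null - pooled[:, :, None], 0.0)
        stat_null = np.sqrt((dev_null**2).sum(axis=1) / k[:, None])
        exceed = (stat_null >= stat[:, None] - 1e-12).sum(axis=1)
        p[idx] = (1.0 + exceed) / (1.0 + num_sims)
    return p, signs


def align_tracks(tracks: dict[str, MethylomeTrack]) -> pd.DataFrame:
    """Outer-join per-sample counts on (chrom, pos).

    Returns a frame with chrom, pos and mc_<sample>/cov_<sample> columns;
    missing sites get zero coverage.
    """
    merged: pd.DataFrame | None = None
    for name, track in tracks.items():
        sub = track.sites[["chrom", "pos", "mc", "cov"]].rename(
            columns={"mc": f"mc_{name}", "cov": f"cov_{name}"}
        )
        merged = sub if merged is None else merged.merge(
            sub, on=["chrom", "pos"], how="outer"
        )
    merged = merged.fillna(0).sort_values(["chrom", "pos"]).reset_index(drop=True)
    for c in merged.columns:
        if c.startswith(("mc_", "cov_")):
            merged[c] = merged[c].astype(int)
    return merged


def call_dmrs(
    tracks: dict[str, MethylomeTrack],
    params: DmrParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Call differentially hypomethylated regions across samples.

    Samples are typically subtype-pooled tracks (replicates combined);
    replicate-level support is re-checked afterwards with
    :func:`require_replicate_support`. Returns one row per DMR with
    per-sample means, hypo_samples (comma-joined), n_sites and the
    minimum member-site p as p_summary.
    """
    params = params or DmrParams()
    if len(tracks) < 2:
        raise ValueError("need >= 2 samples")
    samples = list(tracks)
    aligned = align_tracks(tracks)
    mc = aligned[[f"mc_{s}" for s in samples]].to_numpy(dtype=float)
    cov = aligned[[f"cov_{s}" for s in samples]].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, signs = rms_site_tests(mc, cov, params.num_sims, seed)
    aligned["p"] = p
    sig = (p < params.sig_cutoff) & ~np.isnan(p)

    rows = []
    for chrom, sub in aligned.groupby("chrom", sort=False):
        sidx = sub.index[sig[sub.index]]
        if len(sidx) == 0:
            continue
        pos = aligned.loc[sidx, "pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > params.dmr_max_dist)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            member = sidx[a : b + 1]
            if len(member) < params.min_dms:
                continue
            start, end = int(pos[a]), int(pos[b]) + 1
            in_iv = sub[(sub["pos"] >= start) & (sub["pos"] < end)]
            means = {}
            for j, s in enumerate(samples):
                totc = in_iv[f"cov_{s}"].sum()
                means[s] = in_iv[f"mc_{s}"].sum() / totc if totc > 0 else np.nan
            hypo = []
            for j, s in enumerate(samples):
                others = [means[o] for o in samples if o != s and np.isfinite(means[o])]
                if not others or not np.isfinite(means[s]):
                    continue
                rest = float(np.mean(others))
                neg_major = (signs[member, j] < 0).sum() > len(member) / 2
                if rest - means[s] >= params.min_diff and neg_major:
                    hypo.append(s)
            if not hypo:
                continue
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "n_sites": int(len(member)),
                "hypo_samples": ",".join(hypo),
                "p_summary": float(aligned.loc[member, "p"].min()),
                **{f"mean_{s}": means[s] for s in samples},
            })
    return pd.DataFrame(rows)


def require_replicate_support(
    dmrs: pd.DataFrame,
    replicate_tracks: dict[str, list[MethylomeTrack]],
    params: DmrParams | None = None,
) -> pd.DataFrame:
    """Keep a subtype in hypo_samples only if every replicate supports it.

    For each DMR interval and each candidate subtype S, every replicate
    of S must individually show mean mCG at least min_diff below the
    mean of the other subtypes' (pooled) means over the interval.
    Subtypes with a single replicate are retained with a warning (the
    rule is vacuous there). DMRs whose hypo_samples empties are dropped.
    """
    params = params or DmrParams()
    if len(dmrs) == 0:
        return dmrs.copy()
    singles = [s for s, reps in replicate_tracks.items() if len(reps) < 2]
    if singles:
        warnings.warn(
            f"subtypes with one replicate retained without support check: {singles}",
            stacklevel=2,
        )
    out_rows = []
    subtypes = list(replicate_tracks)
    for _, row in dmrs.iterrows():
        chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
        kept = []
        for s in str(row["hypo_samples"]).split(","):
            if s not in replicate_tracks:
                continue
            rest = [row[f"mean_{o}"] for o in subtypes
                    if o != s and np.isfinite(row.get(f"mean_{o}", np.nan))]
            if len(replicate_tracks[s]) < 2:
                kept.append(s)
                continue
            rest_mean = float(np.mean(rest)) if rest else np.nan
            ok = True
            for rep in replicate_tracks[s]:
                sub = rep.sites
                sel = (sub["chrom"] == chrom) & (sub["pos"] >= start) & (sub["pos"] < end)
                c = sub.loc[sel, "cov"].sum()
                rep_mean = sub.loc[sel, "mc"].sum() / c if c > 0 else np.nan
                if not np.isfinite(rep_mean) or not np.isfinite(rest_mean) \
                        or rest_mean - rep_mean < params.min_diff:
                    ok = False
                    break
            if ok:
                kept.append(s)
        if kept:
            new = row.copy()
            new["hypo_samples"] = ",".join(kept)
            out_rows.append(new)
    return pd.DataFrame(out_rows).reset_index(drop=True)


def assign_ects_hypo_dmrs(
    dmrs: pd.DataFrame, subtypes: list[str]
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Split DMRs into per-subtype all-hypo and uniquely-hypo (ECTS) sets.

    The ECTS set for subtype S contains DMRs with hypo_samples == {S}
    exactly; the all-hypo set those with S among hypo_samples.
    """
    all_hypo, ects = {}, {}
    if len(dmrs) == 0:
        return ({s: dmrs.copy() for s in subtypes},
                {s: dmrs.copy() for s in subtypes})
    hypo_sets = dmrs["hypo_samples"].apply(lambda v: set(str(v).split(",")))
    for s in subtypes:
        all_hypo[s] = dmrs[hypo_sets.apply(lambda x: s in x)].reset_index(drop=True)
        ects[s] = dmrs[hypo_sets.apply(lambda x: x == {s})].reset_index(drop=True)
    return all_hypo, ects


def merge_large_hypo_dmrs(
    dmrs: pd.DataFrame, params: DmrParams | None = None
) -> pd.DataFrame:
    """Union ECTS-hypo-DMRs across gaps <= merge_gap; keep merged runs
    strictly longer than large_min_len bp."""
    params = params or DmrParams()
    if len(dmrs) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_merged"])
    rows = []
    sorted_df = dmrs.sort_values(["chrom", "start", "end"])
    for chrom, sub in sorted_df.groupby("chrom", sort=False):
        cur_start = cur_end = None
        n = 0
        for start, end in zip(sub["start"], sub["end"]):
            if cur_end is None or start - cur_end > params.merge_gap:
                if cur_end is not None and cur_end - cur_start > params.large_min_len:
                    rows.append((chrom, cur_start, cur_end, n))
                cur_start, cur_end, n = int(start), int(end), 1
            else:
                cur_end = max(cur_end, int(end))
                n += 1
        if cur_end is not None and cur_end - cur_start > params.large_min_len:
            rows.append((chrom, cur_start, cur_end, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_merged"])
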