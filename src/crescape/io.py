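"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open (BED convention) everywhere. All
writers transparently gzip when the path ends in ``.gz``.

allc-style methylation tables are TSV with columns
chrom, pos, strand, context, mc, cov; by default the reader pools
strand-symmetric CG calls onto the plus-strand C (the minus-strand G
one bp downstream is added into the plus-strand record).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .methylome import MethylomeTrack
from .motifs import Pwm


def _open(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name, chunks = None, []
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov"]


def write_allc(track: MethylomeTrack, path) -> None:
    df = track.sites.copy()
    df["strand"] = "+"
    df["context"] = "CG"
    df[ALLC_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_allc(path, sample: str = "", replicate: str = "",
              pool_strands: bool = True) -> MethylomeTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=ALLC_COLUMNS,
                     comment="#")
    df = df[df["context"].str.startswith("CG")]
    if pool_strands and (df["strand"] == "-").any():
        minus = df["strand"] == "-"
        df.loc[minus, "pos"] -= 1  # fold the G call onto the plus-strand C
        df = (df.groupby(["chrom", "pos"], as_index=False)[["mc", "cov"]]
                .sum())
    sites = (df[["chrom", "pos", "mc", "cov"]]
             .sort_values(["chrom", "pos"]).reset_index(drop=True))
    return MethylomeTrack(sites, sample=sample, replicate=replicate)


def write_bedgraph(track: MethylomeTrack, path) -> None:
    df = track.sites
    with np.errstate(invalid="ignore"):
        frac = np.where(df["cov"] > 0, df["mc"] / df["cov"].clip(lower=1),
                        np.nan)
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 1,
        "value": np.round(frac, 6),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score", "strand"):
        if extra in df.columns:
            cols.append(extra)
        else:
            break
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_motif(pwm: Pwm, path) -> None:
    """HOMER-style motif text: '>consensus name threshold' + probability rows."""
    with _open(path, "wt") as fh:
        fh.write(f">{pwm.consensus}\t{pwm.name}\t{pwm.default_threshold():.4f}\n")
        for row in pwm.matrix:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_motif(path) -> list[Pwm]:
    pwms: list[Pwm] = []
    name, rows, thresh, maxscore = None, [], None, None

    def flush():
        if name is None:
            return
        mat = np.array(rows, dtype=float)
        pwm = Pwm(name, mat / mat.sum(axis=1, keepdims=True))
        if thresh is not None and pwm.max_score > 0:
            pwm.threshold_frac = min(1.0, thresh / pwm.max_score)
        pwms.append(pwm)

    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("\t")
                name = parts[1] if len(parts) > 1 else parts[0]
                thresh = float(parts[2]) if len(parts) > 2 else None
                rows = []
            else:
                rows.append([float(v) for v in line.split()])
    flush()
    return pwms


def read_expression_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    """Sample manifest TSV: columns sample, replicate, allc_path."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "replicate", "allc_path"}
    if not need <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(need)}")
    return df


def region_bed_with_class(regions: pd.DataFrame) -> pd.DataFrame:
    """Segmentation output as BED6: name=klass, score=round(1000*mean_mcg)."""
    out = regions.copy()
    out["name"] = out.get("klass", "region")
    out["score"] = (1000 * out["mean_mcg"]).round().astype(int)
    out["strand"] = "."
    return out[["chrom", "start", "end", "name", "score", "strand"]]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
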