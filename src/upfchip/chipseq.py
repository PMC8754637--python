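"""ChIP-seq per-base coverage and its depth / input normalizations.

Reads are consumed as BED intervals.  Coverage is the number of intervals
containing each base; depth normalization divides by the total number of
aligned reads, and input normalization divides the IP track base-wise by the
input track.  Bases where the input is zero are masked (NaN) by default, or
stabilised with a pseudocount when requested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import CoverageTrack

__all__ = [
    "read_bed_intervals",
    "write_bed_intervals",
    "coverage_from_reads",
    "depth_normalize",
    "input_normalize",
    "average_tracks",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed_intervals(path: str) -> pd.DataFrame:
    """Read BED intervals (at least 3 columns; 6 when strand is present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed_intervals(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def coverage_from_reads(
    reads: pd.DataFrame, chrom_lengths: dict[str, int], label: str = ""
) -> CoverageTrack:
    """Per-base raw coverage: value at base b = number of intervals containing b."""
    values = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    for chrom, grp in reads.groupby("chrom", sort=False):
        if chrom not in values:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        n = len(values[chrom])
        starts = grp["start"].to_numpy(dtype=int)
        ends = grp["end"].to_numpy(dtype=int)
        if (starts < 0).any() or (ends > n).any() or (starts >= ends).any():
            raise ValueError(f"read interval outside chromosome {chrom!r}")
        diff = np.zeros(n + 1)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        values[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(values, label=label, normalized=False)


def depth_normalize(track: CoverageTrack, total_aligned_reads: int) -> CoverageTrack:
    """Divide every base by the total number of aligned reads."""
    if total_aligned_reads <= 0:
        raise ValueError("total_aligned_reads must be positive")
    values = {c: v / total_aligned_reads for c, v in track.values.items()}
    return CoverageTrack(values, label=track.label, normalized=True)


def input_normalize(
    ip_track: CoverageTrack,
    input_track: CoverageTrack,
    policy: str = "mask",
    epsilon: float = 1e-9,
) -> CoverageTrack:
    """Base-wise IP / input ratio.

    ``policy="mask"`` (default) leaves bases with zero input missing (NaN);
    ``policy="pseudocount"`` computes ``(ip + eps) / (input + eps)``.
    """
    if policy not in ("mask", "pseudocount"):
        raise ValueError(f"unknown zero-input policy {policy!r}")
    if set(ip_track.values) != set(input_track.values):
        raise ValueError("mismatched chromosome sets")
    out: dict[str, np.ndarray] = {}
    for chrom, ip in ip_track.values.items():
        inp = input_track.values[chrom]
        if len(ip) != len(inp):
            raise ValueError(f"length mismatch on {chrom!r}")
        if policy == "mask":
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = ip / inp
            ratio[inp == 0] = np.nan
        else:
            ratio = (ip + epsilon) / (inp + epsilon)
        out[chrom] = ratio
    return CoverageTrack(out, label=f"{ip_track.label}/{input_track.label}", normalized=True)


def average_tracks(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Base-wise arithmetic mean; a base missing in any input stays missing."""
    if not tracks:
        raise ValueError("no tracks to average")
    chroms = set(tracks[0].values)
    for t in tracks[1:]:
        if set(t.values) != chroms:
            raise ValueError("mismatched chromosome sets")
    out = {}
    for chrom in chroms:
        stack = np.vstack([t.values[chrom] for t in tracks])
        out[chrom] = stack.mean(axis=0)  # NaN propagates when missing anywhere
    return CoverageTrack(
        out, label="mean", normalized=all(t.normalized for t in tracks)
    )


def gene_mean_coverage(track: CoverageTrack, annotation) -> pd.Series:
    """Per-gene mean of a track over the gene span, ignoring masked bases."""
    out = {}
    for gene in annotation:
        seg = track.values[gene.chrom][gene.start : gene.end]
        with np.errstate(invalid="ignore"):
            out[gene.gene_id] = float(np.nanmean(seg))
    return pd.Series(out, name="mean_coverage")
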