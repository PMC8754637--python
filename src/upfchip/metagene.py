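"""Metagene profiles.

Two profile kinds are produced:

* ``percent_position`` — tiling-array probes are placed at the percentage
  through their gene of the probe's 5'-most transcribed base, from the TSS
  (0%) to 24 bp upstream of the TES (100%, for 25-mer probes), and averaged
  in 0.1% blocks (1000 bins).

* ``flank_body_flank`` — ChIP-seq coverage averaged per base over a fixed
  upstream flank (TSS-1000..TSS-1), a scaled gene body (1000 fractional
  windows, overlap-weighted), and a fixed downstream flank (TES+1..TES+1000),
  all in transcription direction.

Masked (NaN) bases and flank positions clipped at chromosome edges are
excluded from the means, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import CoverageTrack, Gene, GenomeAnnotation

__all__ = [
    "MetageneProfile",
    "probe_percent_position",
    "build_probe_metagene",
    "build_flank_body_metagene",
]

PERCENT_BINS = 1000


@dataclass
class MetageneProfile:
    kind: str  # "percent_position" | "flank_body_flank"
    bins: np.ndarray  # bin means (NaN where empty)
    bin_counts: np.ndarray  # contributing observations per bin
    axis: np.ndarray  # bin coordinate (percent, or bp/window index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(len(self.bins)),
                "axis": self.axis,
                "mean": self.bins,
                "count": self.bin_counts,
            }
        )


def probe_percent_position(
    position: int, gene: Gene, probe_len: int = 25
) -> float | None:
    """Percent position of a probe's 5'-most transcribed base within a gene.

    *position* is the genomic coordinate of the lowest-coordinate base of
    the probe footprint.  Returns None for probes whose 5'-most base falls
    outside ``[TSS, TES - probe_len + 1]`` in transcription direction.
    """
    length = gene.length
    if length <= probe_len:
        raise ValueError(
            f"gene {gene.gene_id}: length {length} <= probe length {probe_len}"
        )
    if gene.strand == "+":
        u = position - gene.start
    else:
        # 5'-most transcribed base of the footprint is its highest coordinate
        u = (gene.end - 1) - (position + probe_len - 1)
    span = length - probe_len
    if u < 0 or u > span:
        return None
    return 100.0 * u / span


def _percent_bin(u: int, span: int, n_bins: int = PERCENT_BINS) -> int:
    """Half-open 0.1% bins, with 100% assigned to the final bin."""
    return min((n_bins * u) // span, n_bins - 1)


def build_probe_metagene(
    normalized_probes: pd.DataFrame,
    annotation: GenomeAnnotation,
    probe_len: int = 25,
) -> MetageneProfile:
    """Pool in-range probes of all genes into 0.1% blocks of gene bodies."""
    sums = np.zeros(PERCENT_BINS)
    counts = np.zeros(PERCENT_BINS, dtype=int)
    for row in normalized_probes.itertuples(index=False):
        if row.gene_id not in annotation:
            continue
        gene = annotation[row.gene_id]
        if gene.length <= probe_len:
            continue
        if gene.strand == "+":
            u = row.position - gene.start
        else:
            u = (gene.end - 1) - (row.position + probe_len - 1)
        span = gene.length - probe_len
        if u < 0 or u > span:
            continue
        b = _percent_bin(u, span)
        sums[b] += row.value
        counts[b] += 1
    if counts.sum() == 0:
        raise ValueError("no in-range probes")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    axis = (np.arange(PERCENT_BINS) + 0.5) * (100.0 / PERCENT_BINS)
    return MetageneProfile("percent_position", means, counts, axis)


def _oriented_flank(
    values: np.ndarray, gene: Gene, flank: int, upstream: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bp flank values in transcription direction plus a validity mask.

    Entry 0 of an upstream flank is the position ``flank`` bp before the
    TSS; entry 0 of a downstream flank is 1 bp past the TES.  Positions
    clipped at the chromosome edge are invalid.
    """
    n = len(values)
    out = np.full(flank, np.nan)
    valid = np.zeros(flank, dtype=bool)
    forward = (gene.strand == "+") == upstream  # genomic left side of the gene
    if forward:
        anchor = gene.start  # positions anchor-flank .. anchor-1
        lo = max(0, anchor - flank)
        seg = values[lo:anchor]
        k = len(seg)
        if gene.strand == "+":
            out[flank - k :] = seg
            valid[flank - k :] = True
        else:  # downstream flank of a minus-strand gene, reversed
            out[:k] = seg[::-1]
            valid[:k] = True
    else:
        anchor = gene.end  # positions anchor .. anchor+flank-1
        hi = min(n, anchor + flank)
        seg = values[anchor:hi]
        k = len(seg)
        if gene.strand == "+":
            out[:k] = seg
            valid[:k] = True
        else:  # upstream flank of a minus-strand gene, reversed
            out[flank - k :] = seg[::-1]
            valid[flank - k :] = True
    valid &= ~np.isnan(out)
    return out, valid


def _body_window_means(
    values: np.ndarray, gene: Gene, body_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap-weighted window means of the gene body in transcription order."""
    seg = values[gene.start : gene.end]
    if gene.strand == "-":
        seg = seg[::-1]
    L = len(seg)
    mask = ~np.isnan(seg)
    v = np.where(mask, seg, 0.0)
    # integral of v and of mask from 0 to x (x in bases, piecewise linear)
    cum_v = np.concatenate([[0.0], np.cumsum(v)])
    cum_m = np.concatenate([[0.0], np.cumsum(mask.astype(float))])

    def integral(cum, base, x):
        i = np.minimum(x.astype(int), L - 1)
        frac = x - i
        return cum[i] + frac * base[i]

    edges = np.linspace(0.0, L, body_bins + 1)
    edges[-1] = L
    iv = np.concatenate([integral(cum_v, v, edges[:-1]), [cum_v[-1]]])
    im = np.concatenate([integral(cum_m, mask.astype(float), edges[:-1]), [cum_m[-1]]])
    dv = np.diff(iv)
    dm = np.diff(im)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(dm > 0, dv / np.where(dm > 0, dm, 1.0), np.nan)
    return means, dm > 0


def build_flank_body_metagene(
    track: CoverageTrack,
    annotation: GenomeAnnotation,
    flank: int = 1000,
    body_bins: int = 1000,
    min_gene_length: int | None = None,
) -> MetageneProfile:
    """Fixed-flank / scaled-body profile of a normalized coverage track.

    Genes shorter than ``body_bins / 10`` bp are excluded.  Each gene
    contributes one observation per flank base and one per body window.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    if min_gene_length is None:
        min_gene_length = body_bins // 10
    total = flank + body_bins + flank
    sums = np.zeros(total)
    counts = np.zeros(total, dtype=int)
    used = 0
    for gene in annotation:
        if gene.length < min_gene_length:
            continue
        values = track.values[gene.chrom]
        up, up_ok = _oriented_flank(values, gene, flank, upstream=True)
        body, body_ok = _body_window_means(values, gene, body_bins)
        down, down_ok = _oriented_flank(values, gene, flank, upstream=False)
        row = np.concatenate([up, body, down])
        ok = np.concatenate([up_ok, body_ok, down_ok])
        sums[ok] += row[ok]
        counts[ok] += 1
        used += 1
    if used == 0:
        raise ValueError("no genes pass the length filter")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    axis = np.concatenate(
        [
            np.arange(-flank, 0, dtype=float),
            (np.arange(body_bins) + 0.5) * (100.0 / body_bins),
            np.arange(1, flank + 1, dtype=float),
        ]
    )
    return MetageneProfile("flank_body_flank", means, counts, axis)
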