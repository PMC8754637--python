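"""Tiling-array (ChIP-chip) signal processing and enriched-gene calling.

Probe-level PM/MM intensities are summarised into a per-gene signal with a
simplified MAS5-style estimator (ideal-mismatch correction, log2 probe
values, one-step Tukey biweight).  Arrays are put on a common scale by
median scaling, replicates averaged, and IP signals divided by their control
to give per-gene normalized signals.

Enriched genes are called with a sliding-window trimmed-mean statistic on
robustly standardized log probe values.  A gene is enriched when merged
significant regions cover at least half of its length; its enrichment score
is the mean normalized probe value over the merged region span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation, UNASSIGNED

__all__ = [
    "GeneSignalTable",
    "EnrichedCall",
    "summarize_gene_signal",
    "gene_signal_table",
    "scale_to_common_median",
    "average_tables",
    "normalize_by_control",
    "probe_normalized_values",
    "call_enriched_genes",
    "enriched_calls_frame",
]

PROBE_LEN = 25
_LOG_FLOOR = 2.0 ** -20  # floor on pm - IM before taking log2
_BIWEIGHT_C = 5.0
_BIWEIGHT_EPS = 1e-4


@dataclass
class GeneSignalTable:
    """Per-gene scalar signals for one assay.

    ``origin`` is ``ip``, ``control`` or ``normalized``; normalized tables
    record which control they were divided by.
    """

    signal: pd.Series  # index: gene_id, values positive
    origin: str
    assay: str = ""
    control_ref: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("ip", "control", "normalized"):
            raise ValueError(f"invalid origin {self.origin!r}")
        if self.signal.index.has_duplicates:
            raise ValueError("gene appears twice in signal table")
        self.signal = self.signal.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.signal.index


@dataclass(frozen=True)
class EnrichedCall:
    gene_id: str
    enriched: bool
    fraction_significant: float
    enrichment_score: float
    region_start: int | None
    region_end: int | None


def _tukey_biweight(x: np.ndarray, c: float = _BIWEIGHT_C, eps: float = _BIWEIGHT_EPS) -> float:
    """One-step Tukey biweight location around the median with MAD scale."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    s = np.median(np.abs(x - med))
    u = (x - med) / (c * s + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def summarize_gene_signal(pm: np.ndarray, mm: np.ndarray) -> float:
    """MAS5-style signal for one gene on one array.

    Per probe pair the ideal mismatch is ``mm`` when ``mm < pm`` and
    ``pm / 2`` otherwise; the probe value is ``log2(pm - IM)`` floored at
    ``2**-20``; the signal is ``2**biweight`` of the probe values.
    """
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.size == 0:
        raise ValueError("gene has no probe pairs")
    im = np.where(mm < pm, mm, pm / 2.0)
    pv = np.log2(np.maximum(pm - im, _LOG_FLOOR))
    return float(2.0 ** _tukey_biweight(pv))


def gene_signal_table(
    probes: pd.DataFrame,
    origin: str,
    assay: str = "",
    min_probes: int = 1,
) -> GeneSignalTable:
    """Summarise a probe table into per-gene MAS5-style signals.

    Probes in the ``unassigned`` group are skipped; genes with fewer than
    *min_probes* probes are dropped.
    """
    out: dict[str, float] = {}
    for gene_id, grp in probes.groupby("gene_id", sort=True):
        if gene_id == UNASSIGNED:
            continue
        if len(grp) < min_probes:
            continue
        out[gene_id] = summarize_gene_signal(grp["pm"].to_numpy(), grp["mm"].to_numpy())
    return GeneSignalTable(pd.Series(out, name="signal"), origin=origin, assay=assay)


def _check_same_genes(a: GeneSignalTable, b: GeneSignalTable) -> None:
    if not a.signal.index.sort_values().equals(b.signal.index.sort_values()):
        only_a = a.signal.index.difference(b.signal.index)
        only_b = b.signal.index.difference(a.signal.index)
        raise ValueError(
            f"gene sets differ: {list(only_a[:5])} only in first, "
            f"{list(only_b[:5])} only in second"
        )


def scale_to_common_median(
    table_a: GeneSignalTable, table_b: GeneSignalTable
) -> tuple[GeneSignalTable, GeneSignalTable]:
    """Scale two tables so both medians equal the mean of the two medians."""
    _check_same_genes(table_a, table_b)
    med_a = float(table_a.signal.median())
    med_b = float(table_b.signal.median())
    if med_a <= 0 or med_b <= 0:
        raise ValueError("median must be positive for scaling")
    target = (med_a + med_b) / 2.0
    scaled_a = GeneSignalTable(table_a.signal * (target / med_a), table_a.origin, table_a.assay)
    scaled_b = GeneSignalTable(table_b.signal * (target / med_b), table_b.origin, table_b.assay)
    return scaled_a, scaled_b


def average_tables(tables: list[GeneSignalTable]) -> GeneSignalTable:
    """Per-gene arithmetic mean across replicate tables."""
    if not tables:
        raise ValueError("no tables to average")
    first = tables[0]
    for t in tables[1:]:
        _check_same_genes(first, t)
    stacked = pd.concat([t.signal.sort_index() for t in tables], axis=1)
    return GeneSignalTable(stacked.mean(axis=1), first.origin, first.assay)


def normalize_by_control(
    ip_table: GeneSignalTable, control_table: GeneSignalTable
) -> GeneSignalTable:
    """Divide per-gene IP signal by the control signal.

    Genes with non-positive control signal are dropped (flagged missing).
    """
    _check_same_genes(ip_table, control_table)
    ctl = control_table.signal
    bad = ctl <= 0
    ratio = ip_table.signal[~bad] / ctl[~bad]
    out = GeneSignalTable(
        ratio, origin="normalized", assay=ip_table.assay, control_ref=control_table.assay
    )
    return out


def probe_normalized_values(
    ip_arrays: list[pd.DataFrame], control_arrays: list[pd.DataFrame]
) -> pd.DataFrame:
    """Per-probe PM/MM ratios, divided by the control mean ratio.

    Each array's per-probe ratio is PM / MM.  The control arrays' ratios are
    averaged into a control mean per probe; each IP array's ratio is divided
    by it, and multiple IP arrays are averaged probe-wise.
    """
    if not ip_arrays or not control_arrays:
        raise ValueError("need at least one IP and one control array")
    ref = ip_arrays[0].set_index("probe_id")
    ref_ids = ref.index
    def _ratio(df: pd.DataFrame) -> pd.Series:
        d = df.set_index("probe_id")
        if not d.index.sort_values().equals(ref_ids.sort_values()):
            raise ValueError("probe sets differ between arrays")
        d = d.loc[ref_ids]
        return d["pm"] / d["mm"]

    control_mean = pd.concat([_ratio(a) for a in control_arrays], axis=1).mean(axis=1)
    normed = pd.concat([_ratio(a) / control_mean for a in ip_arrays], axis=1).mean(axis=1)
    out = ref[["chrom", "position", "strand", "gene_id"]].copy()
    out["value"] = normed
    return out.reset_index()


# ---------------------------------------------------------------------------
# Enriched-gene calling
# ---------------------------------------------------------------------------


def _robust_z(scores: np.ndarray) -> np.ndarray:
    med = np.median(scores)
    mad = np.median(np.abs(scores - med)) * 1.4826
    if mad == 0:
        mad = float(np.std(scores))
        if mad == 0:
            raise ValueError("degenerate probe scores: zero MAD and zero SD")
    return (scores - med) / mad


def _window_pvalues(
    pos: np.ndarray, z: np.ndarray, window_bp: float, trim: float = 0.1
) -> np.ndarray:
    """One-sided P per probe from the trimmed mean of z within +-window_bp/2."""
    half = window_bp / 2.0
    left = np.searchsorted(pos, pos - half, side="left")
    right = np.searchsorted(pos, pos + half, side="right")
    stat = np.empty(len(pos))
    for i in range(len(pos)):
        w = z[left[i] : right[i]]
        k = int(trim * len(w))
        if k > 0:
            w = np.sort(w)[k : len(w) - k]
        stat[i] = w.mean() * np.sqrt(len(w))
    return stats.norm.sf(stat)


def _merge_regions(
    pos: np.ndarray, maxgap_bp: float, probe_len: int = PROBE_LEN
) -> list[tuple[int, int]]:
    """Merge significant probe positions within maxgap into regions."""
    if len(pos) == 0:
        return []
    regions = []
    start = prev = pos[0]
    for p in pos[1:]:
        if p - prev > maxgap_bp:
            regions.append((int(start), int(prev) + probe_len))
            start = p
        prev = p
    regions.append((int(start), int(prev) + probe_len))
    return regions


def call_enriched_genes(
    normalized_probes: pd.DataFrame,
    annotation: GenomeAnnotation,
    p_cutoff: float = 1e-3,
    window_bp: float = 300.0,
    maxgap_bp: float = 300.0,
    probe_len: int = PROBE_LEN,
) -> list[EnrichedCall]:
    """Call genes enriched by the windowed trimmed-mean probe statistic.

    Probe scores are log normalized values, standardized genome-wide by
    median/MAD.  The per-probe statistic is the 10%-trimmed mean of scores
    within ``window_bp`` centred on the probe, scaled by sqrt(effective n);
    its one-sided normal P below *p_cutoff* marks the probe significant.
    Significant probes within *maxgap_bp* merge into regions; a gene is
    enriched when regions cover >= 50% of its length.
    """
    if not 0 < p_cutoff < 1:
        raise ValueError("p_cutoff must be in (0, 1)")
    if len(normalized_probes) == 0:
        raise ValueError("empty probe set")
    df = normalized_probes.sort_values(["chrom", "position"], kind="mergesort")
    scores = np.log(df["value"].to_numpy())
    z = _robust_z(scores)
    df = df.assign(_z=z)

    sig_by_chrom: dict[str, list[tuple[int, int]]] = {}
    probe_pos: dict[str, np.ndarray] = {}
    probe_val: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["position"].to_numpy()
        pv = _window_pvalues(pos, grp["_z"].to_numpy(), window_bp)
        sig_by_chrom[chrom] = _merge_regions(pos[pv < p_cutoff], maxgap_bp, probe_len)
        probe_pos[chrom] = pos
        probe_val[chrom] = grp["value"].to_numpy()

    calls: list[EnrichedCall] = []
    for gene in annotation:
        regions = sig_by_chrom.get(gene.chrom, [])
        overlapping = [
            (s, e) for s, e in regions if s < gene.end and e > gene.start
        ]
        covered = sum(
            min(e, gene.end) - max(s, gene.start) for s, e in overlapping
        )
        frac = covered / gene.length
        if overlapping:
            span_start = min(s for s, _ in overlapping)
            span_end = max(e for _, e in overlapping)
            pos = probe_pos[gene.chrom]
            inside = np.zeros(len(pos), dtype=bool)
            for s, e in overlapping:
                inside |= (pos >= s) & (pos < e)
            score = float(probe_val[gene.chrom][inside].mean())
        else:
            span_start = span_end = None
            score = float("nan")
        calls.append(
            EnrichedCall(
                gene_id=gene.gene_id,
                enriched=frac >= 0.5,
                fraction_significant=float(frac),
                enrichment_score=score,
                region_start=span_start,
                region_end=span_end,
            )
        )
    return calls


def enriched_calls_frame(calls: list[EnrichedCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "enriched": [c.enriched for c in calls],
            "fraction_significant": [c.fraction_significant for c in calls],
            "enrichment_score": [c.enrichment_score for c in calls],
            "region_start": [c.region_start for c in calls],
            "region_end": [c.region_end for c in calls],
        }
    )
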