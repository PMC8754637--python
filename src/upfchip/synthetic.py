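"""Synthetic-data generators with planted, recorded ground truth.

The generators emulate the statistical structure the occupancy analysis
assumes: per-gene latent transcription rates, Pol II occupancy proportional
to the rate, Upf1 occupancy coupled to Pol II on a bound subset and at
background on the rest, PM/MM tiling-probe intensities with multiplicative
log-normal noise, ~500 bp fragment ChIP-seq reads for IP and input,
replicate FPKM values, and differential-expression labels with a planted
overlap with the bound set.

Two coupling modes are available for the Upf1/Pol II relationship.  With an
explicit ``sigma_eps`` the bound-gene occupancy is ``tau**beta * exp(eps)``
with fixed log-normal noise — the mode used for detection-recovery studies.
With ``rho_target`` given instead, ``sigma_eps`` is solved numerically so
that the realized Spearman correlation between Upf1 and Pol II occupancy
over all genes matches the target; the solved value and the realized
correlation are recorded in the ground truth.

All generators are pure functions of (seed, parameters); a single root seed
derives fixed per-component child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import spearmanr

from .annotation import Gene, GenomeAnnotation, UNASSIGNED

__all__ = [
    "GroundTruth",
    "child_seed",
    "simulate_annotation",
    "simulate_occupancy",
    "simulate_probe_array",
    "simulate_chipseq",
    "simulate_expression",
    "simulate_de_labels",
]

# fixed offsets deriving per-component child seeds from the root seed
SEED_OFFSETS = {
    "annotation": 11,
    "occupancy": 23,
    "probe_array": 37,
    "chipseq": 47,
    "expression": 59,
    "de_labels": 71,
}
_SEED_MOD = 2**31 - 1


def child_seed(root_seed: int, component: str) -> int:
    return (int(root_seed) * 1000003 + SEED_OFFSETS[component]) % _SEED_MOD


@dataclass
class GroundTruth:
    """Planted per-gene latent quantities plus generation parameters.

    ``table`` columns: gene_id, tau, polii_occupancy, upf1_occupancy, bound,
    group_label, fpkm_true, de_flag, de_direction.
    """

    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def occupancy(self, target: str) -> pd.Series:
        col = {"upf1": "upf1_occupancy", "polii": "polii_occupancy"}[target]
        return self.table.set_index("gene_id")[col]

    @property
    def bound_genes(self) -> set[str]:
        return set(self.table.loc[self.table["bound"], "gene_id"])


def simulate_annotation(
    seed: int,
    n_genes: int,
    n_chroms: int = 3,
    length_median: float = 1500.0,
    length_sigma: float = 0.5,
    length_bounds: tuple[int, int] = (300, 8000),
    min_gap: int = 200,
    gap_mean: float = 300.0,
    chrom_length: int | None = None,
) -> GenomeAnnotation:
    """Non-overlapping genes with log-normal lengths and >= *min_gap* gaps.

    Genes are laid out sequentially, round-robin over chromosomes, with
    intergenic gaps of ``min_gap`` plus an exponential excess.  When
    *chrom_length* is given and the genes do not fit, an error is raised;
    otherwise chromosomes are sized to what was placed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.clip(
        rng.lognormal(np.log(length_median), length_sigma, n_genes),
        *length_bounds,
    ).astype(int)
    gaps = (min_gap + rng.exponential(gap_mean, n_genes + 1)).astype(int)
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    genes: list[Gene] = []
    cursor = {f"chr{i + 1}": 0 for i in range(n_chroms)}
    chroms = list(cursor)
    width = len(str(n_genes))
    for i in range(n_genes):
        chrom = chroms[i % n_chroms]
        start = cursor[chrom] + gaps[i]
        end = start + lengths[i]
        if chrom_length is not None and end > chrom_length:
            raise ValueError(
                f"requested genes do not fit: gene {i} ends at {end} on {chrom} "
                f"(chrom_length={chrom_length})"
            )
        genes.append(
            Gene(f"g{str(i + 1).zfill(width)}", chrom, int(start), int(end), strands[i])
        )
        cursor[chrom] = int(end)
    tail = int(min_gap + gap_mean)
    if chrom_length is not None:
        chrom_lengths = {c: int(chrom_length) for c in chroms}
    else:
        chrom_lengths = {c: cursor[c] + tail for c in chroms}
    return GenomeAnnotation(genes, chrom_lengths)


def simulate_occupancy(
    seed: int,
    annotation: GenomeAnnotation,
    frac_bound: float = 0.3,
    rho_target: float | None = None,
    sigma_eps: float = 0.3,
    beta: float = 1.0,
    tau_sigma: float = 1.0,
    background: float = 0.05,
    ratio_thresholds: tuple[float, float] = (-1.0, 1.0),
    fpkm_scale: float = 10.0,
) -> GroundTruth:
    """Draw latent transcription rates and Upf1 / Pol II occupancies.

    tau is log-normal (median 1).  Pol II occupancy equals tau.  The bound
    subset is the top *frac_bound* of genes by tau — co-transcriptional
    recruitment places Upf1 on the transcribed part of the genome — with
    ``upf1 = tau**beta * exp(eps)``; unbound genes sit strictly below the
    recorded *background* occupancy.  When *rho_target* is given, the noise
    scale is solved so the realized Spearman(upf1, polII) over all genes
    matches it.  Group labels follow log2(upf1 / polII) against
    *ratio_thresholds*.
    """
    if not 0 <= frac_bound <= 1:
        raise ValueError("frac_bound must be in [0, 1]")
    if rho_target is not None and not 0 < rho_target < 1:
        raise ValueError("rho_target must be in (0, 1)")
    theta_low, theta_high = ratio_thresholds
    if theta_low >= theta_high:
        raise ValueError("ratio_thresholds must be (low, high) with low < high")
    n = len(annotation)
    rng = np.random.default_rng(seed)
    tau = rng.lognormal(0.0, tau_sigma, n)
    polii = tau.copy()
    n_bound = int(round(frac_bound * n))
    bound = np.zeros(n, dtype=bool)
    bound[np.argsort(tau)[n - n_bound :]] = True if n_bound else False
    upf1 = background * rng.uniform(0.25, 1.0, n)  # strictly below background
    z = rng.standard_normal(n)

    def _upf1(sigma: float) -> np.ndarray:
        u = upf1.copy()
        u[bound] = tau[bound] ** beta * np.exp(sigma * z[bound])
        return u

    if n_bound == 0:
        sigma = 0.0
    elif rho_target is None:
        sigma = float(sigma_eps)
    else:
        def gap(sigma: float) -> float:
            return spearmanr(_upf1(sigma), polii).statistic - rho_target

        hi = 8.0
        if gap(0.0) <= 0 or gap(hi) >= 0:
            raise ValueError(
                f"rho_target={rho_target} not attainable at frac_bound={frac_bound}"
            )
        sigma = float(brentq(gap, 0.0, hi, xtol=1e-4))
    upf1 = _upf1(sigma)
    realized_rho = float(spearmanr(upf1, polii).statistic) if n >= 3 else float("nan")

    d = np.log2(upf1) - np.log2(polii)
    group = np.where(d >= theta_high, "high_ratio",
                     np.where(d <= theta_low, "low_ratio", "similar"))
    table = pd.DataFrame(
        {
            "gene_id": annotation.gene_ids,
            "tau": tau,
            "polii_occupancy": polii,
            "upf1_occupancy": upf1,
            "bound": bound,
            "group_label": group,
            "fpkm_true": fpkm_scale * tau,
            "de_flag": False,
            "de_direction": "none",
        }
    )
    params = {
        "seed": int(seed),
        "frac_bound": float(frac_bound),
        "rho_target": rho_target,
        "sigma_eps": sigma,
        "beta": float(beta),
        "tau_sigma": float(tau_sigma),
        "background": float(background),
        "ratio_thresholds": (float(theta_low), float(theta_high)),
        "realized_rho": realized_rho,
        "fpkm_scale": float(fpkm_scale),
    }
    return GroundTruth(table, params)


def _occupancy_per_base(
    annotation: GenomeAnnotation, occ: pd.Series, smooth_bp: int = 0
) -> dict[str, np.ndarray]:
    """Paint per-gene occupancy on gene spans; optionally smooth with a
    moving average of *smooth_bp* bases (mimicking ~500 bp ChIP fragments
    spreading enrichment across gene boundaries)."""
    tracks = {c: np.zeros(n) for c, n in annotation.chrom_lengths.items()}
    for gene in annotation:
        tracks[gene.chrom][gene.start : gene.end] = occ[gene.gene_id]
    if smooth_bp > 1:
        kernel = np.ones(smooth_bp) / smooth_bp
        tracks = {c: np.convolve(v, kernel, mode="same") for c, v in tracks.items()}
    return tracks


def simulate_probe_array(
    seed: int,
    annotation: GenomeAnnotation,
    truth: GroundTruth | None,
    spacing: int = 20,
    probe_len: int = 25,
    background_intensity: float = 100.0,
    kappa: float = 0.7,
    gain: float = 5.0,
    sigma_eta: float = 0.3,
    smooth_bp: int = 500,
    target: str = "upf1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PM/MM probe tables for one IP array and one paired control array.

    Probes tile genes and intergenic gaps every *spacing* bp.  For the IP
    array ``PM = B * exp(eta) * (1 + gain * occ_local)`` with occ_local the
    occupancy painted on gene spans and smoothed by a *smooth_bp* moving
    average; ``MM = B * kappa * exp(eta')``.  The control array is generated
    with occ_local = 0.  Passing ``truth=None`` also yields a null array.
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    rng = np.random.default_rng(seed)
    if truth is not None:
        occ = truth.occupancy(target)
        tracks = _occupancy_per_base(annotation, occ, smooth_bp)
    else:
        tracks = {c: np.zeros(n) for c, n in annotation.chrom_lengths.items()}

    rows_ip, rows_ctl = [], []
    for chrom in sorted(annotation.chrom_lengths):
        n = annotation.chrom_lengths[chrom]
        positions = np.arange(0, n - probe_len + 1, spacing)
        occ_local = tracks[chrom][positions]
        m = len(positions)
        eta = rng.normal(0.0, sigma_eta, (4, m))  # ip pm, ip mm, ctl pm, ctl mm
        pm_ip = background_intensity * np.exp(eta[0]) * (1.0 + gain * occ_local)
        mm_ip = background_intensity * kappa * np.exp(eta[1])
        pm_ctl = background_intensity * np.exp(eta[2])
        mm_ctl = background_intensity * kappa * np.exp(eta[3])
        gene_ids = np.full(m, UNASSIGNED, dtype=object)
        for gene in annotation:
            if gene.chrom != chrom:
                continue
            sel = (positions >= gene.start) & (positions < gene.end)
            gene_ids[sel] = gene.gene_id
        probe_ids = [f"pr_{chrom}_{p}" for p in positions]
        strands = np.full(m, "+")
        rows_ip.append(
            pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "chrom": chrom,
                    "position": positions,
                    "strand": strands,
                    "pm": pm_ip,
                    "mm": mm_ip,
                    "gene_id": gene_ids,
                }
            )
        )
        rows_ctl.append(
            pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "chrom": chrom,
                    "position": positions,
                    "strand": strands,
                    "pm": pm_ctl,
                    "mm": mm_ctl,
                    "gene_id": gene_ids,
                }
            )
        )
    ip = pd.concat(rows_ip, ignore_index=True)
    ctl = pd.concat(rows_ctl, ignore_index=True)
    return ip, ctl


def simulate_chipseq(
    seed: int,
    annotation: GenomeAnnotation,
    truth: GroundTruth | None,
    n_reads: int,
    fragment_mean: float = 500.0,
    fragment_sd: float = 100.0,
    read_len: int = 50,
    occupancy_floor: float = 0.1,
    smooth_bp: int = 500,
    target: str = "polii",
    max_retries: int = 100,
) -> pd.DataFrame:
    """BED reads for one sample.

    Fragment midpoints are drawn proportional to ``occupancy + floor``
    (uniform for an input sample: pass ``truth=None``); fragment lengths are
    normal, truncated at *read_len*; each fragment yields one *read_len*
    read from its 5' end on a random strand.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = sorted(annotation.chrom_lengths)
    if truth is not None:
        occ = truth.occupancy(target)
        tracks = _occupancy_per_base(annotation, occ, smooth_bp)
        weights = {c: tracks[c] + occupancy_floor for c in chroms}
    else:
        weights = {c: np.ones(annotation.chrom_lengths[c]) for c in chroms}
    totals = np.array([weights[c].sum() for c in chroms])
    n_per_chrom = rng.multinomial(n_reads, totals / totals.sum())

    frames = []
    for chrom, n_c in zip(chroms, n_per_chrom):
        if n_c == 0:
            continue
        clen = annotation.chrom_lengths[chrom]
        cdf = np.cumsum(weights[chrom])
        cdf /= cdf[-1]
        mids = np.searchsorted(cdf, rng.random(n_c))
        flen = np.maximum(
            rng.normal(fragment_mean, fragment_sd, n_c), read_len
        ).astype(int)
        starts = mids - flen // 2
        ends = starts + flen
        bad = (starts < 0) | (ends > clen)
        tries = 0
        while bad.any():
            tries += 1
            if tries > max_retries:
                raise ValueError(
                    f"chromosome {chrom} too short for fragments after "
                    f"{max_retries} retries"
                )
            nb = int(bad.sum())
            mids_b = np.searchsorted(cdf, rng.random(nb))
            flen_b = np.maximum(
                rng.normal(fragment_mean, fragment_sd, nb), read_len
            ).astype(int)
            starts[bad] = mids_b - flen_b // 2
            ends[bad] = starts[bad] + flen_b
            bad = (starts < 0) | (ends > clen)
        strands = np.where(rng.random(n_c) < 0.5, "+", "-")
        read_start = np.where(strands == "+", starts, ends - read_len)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": read_start,
                    "end": read_start + read_len,
                    "name": [f"read_{chrom}_{i}" for i in range(n_c)],
                    "score": 0,
                    "strand": strands,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_expression(
    seed: int, truth: GroundTruth, n_replicates: int = 2, dispersion: float = 0.2
) -> pd.DataFrame:
    """Replicate FPKM values: ``fpkm_true * exp(eps)`` per replicate."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    fpkm_true = truth.table["fpkm_true"].to_numpy()
    out = {"gene_id": truth.table["gene_id"]}
    for r in range(n_replicates):
        eps = rng.normal(0.0, dispersion, len(fpkm_true))
        out[f"fpkm_{r + 1}"] = fpkm_true * np.exp(eps)
    return pd.DataFrame(out)


def simulate_de_labels(
    seed: int,
    truth: GroundTruth,
    n_de: int,
    frac_up: float = 0.7,
    planted_overlap: int = 0,
) -> pd.DataFrame:
    """Differential-expression labels with a planted overlap with bound genes.

    Exactly *n_de* genes are labelled DE, exactly *planted_overlap* of them
    drawn from the bound subset, the rest from unbound genes; direction is
    up with probability *frac_up*.  The truth table is updated in place.
    """
    rng = np.random.default_rng(seed)
    tab = truth.table
    bound_ids = tab.loc[tab["bound"], "gene_id"].to_numpy()
    unbound_ids = tab.loc[~tab["bound"], "gene_id"].to_numpy()
    if planted_overlap > min(n_de, len(bound_ids)):
        raise ValueError("planted_overlap exceeds n_de or number of bound genes")
    if n_de - planted_overlap > len(unbound_ids):
        raise ValueError("not enough unbound genes for requested DE labels")
    chosen = np.concatenate(
        [
            rng.choice(bound_ids, planted_overlap, replace=False),
            rng.choice(unbound_ids, n_de - planted_overlap, replace=False),
        ]
    )
    direction = np.where(rng.random(n_de) < frac_up, "up", "down")
    tab["de_flag"] = tab["gene_id"].isin(chosen)
    dmap = dict(zip(chosen, direction))
    tab["de_direction"] = tab["gene_id"].map(lambda g: dmap.get(g, "none"))
    truth.params.update(
        {"n_de": int(n_de), "planted_overlap": int(planted_overlap), "frac_up": float(frac_up)}
    )
    return pd.DataFrame({"gene_id": chosen, "direction": direction})
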