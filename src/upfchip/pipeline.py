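"""End-to-end orchestration: config, stages, manifest.

Stages run in dependency order on files in one output directory so that any
stage can be re-run alone and reproduce its artifacts byte-identically.  All
randomness flows from one root seed via fixed per-component child seeds; the
manifest records the configuration, a hash of it, and every artifact.

The simulated experiment mirrors the array design of the study the pipeline
models: one Upf1 IP array with a pair of control arrays, and a pair of
Pol II IP arrays with their own control pair (control and IP pairs are
median-scaled to each other and averaged before normalization).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import annotation as anno
from . import association, chipchip, chipseq, metagene, synthetic

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("upfchip")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_genes": 200,
        "n_chroms": 3,
        "frac_bound": 0.3,
        "rho_target": None,  # calibrate sigma_eps when set
        "sigma_eps": 0.3,
        "tau_sigma": 1.0,
        "background": 0.05,
        "ratio_thresholds": [-1.0, 1.0],
        "probe_spacing": 20,
        "probe_gain": 5.0,
        "probe_sigma_eta": 0.3,
        "probe_kappa": 0.7,
        "chipseq_reads": 50000,
        "fragment_mean": 500.0,
        "fragment_sd": 100.0,
        "read_len": 50,
        "n_replicates": 2,
        "fpkm_dispersion": 0.2,
        "n_de": 30,
        "planted_overlap": 10,
        "frac_up": 0.7,
    },
    "enrichment": {"p_cutoff": 1e-3, "p_cutoff_strict": 1e-4,
                   "window_bp": 300.0, "maxgap_bp": 300.0},
    "coverage": {"policy": "mask", "epsilon": 1e-9},
    "correlate": {"top_expressed_fraction": 0.9},
    "classify": {"theta_low": -1.0, "theta_high": 1.0, "min_signal": 0.1},
    "overlap": {"reps": 1000},
}


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides onto the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base: dict, extra: dict) -> None:
        for k, v in extra.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                merge(base[k], v)
            else:
                base[k] = v

    if path is not None:
        import yaml

        with open(path) as fh:
            merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        merge(cfg, overrides)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _Run:
    """Shared state of one pipeline run: config, outdir, manifest entries."""

    def __init__(self, config: dict, outdir: str):
        self.cfg = config
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.artifacts: list[str] = []
        self.counts: dict[str, int] = {}

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def record(self, name: str) -> str:
        if name not in self.artifacts:
            self.artifacts.append(name)
        return self.path(name)

    def annotation(self) -> anno.GenomeAnnotation:
        lengths = json.load(open(self.path("chrom_lengths.json")))
        return anno.load_annotation(self.path("annotation.gff3"), "gff3", lengths)

    def probe(self, name: str) -> pd.DataFrame:
        return anno.load_probe_table(self.path(name))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(run: _Run) -> None:
    cfg = run.cfg["simulate"]
    seed = run.cfg["seed"]
    ann = synthetic.simulate_annotation(
        synthetic.child_seed(seed, "annotation"),
        n_genes=cfg["n_genes"],
        n_chroms=cfg["n_chroms"],
    )
    anno.write_annotation(ann, run.record("annotation.gff3"), "gff3")
    anno.write_annotation(ann, run.record("annotation.bed"), "bed")
    json.dump(ann.chrom_lengths, open(run.record("chrom_lengths.json"), "w"), indent=0)

    truth = synthetic.simulate_occupancy(
        synthetic.child_seed(seed, "occupancy"),
        ann,
        frac_bound=cfg["frac_bound"],
        rho_target=cfg["rho_target"],
        sigma_eps=cfg["sigma_eps"],
        tau_sigma=cfg["tau_sigma"],
        background=cfg["background"],
        ratio_thresholds=tuple(cfg["ratio_thresholds"]),
    )
    truth.table.to_csv(run.record("ground_truth.tsv"), sep="\t", index=False)

    array_kw = dict(
        spacing=cfg["probe_spacing"],
        gain=cfg["probe_gain"],
        sigma_eta=cfg["probe_sigma_eta"],
        kappa=cfg["probe_kappa"],
    )
    base = synthetic.child_seed(seed, "probe_array")
    upf_ip, upf_ctl1 = synthetic.simulate_probe_array(
        base, ann, truth, target="upf1", **array_kw
    )
    _, upf_ctl2 = synthetic.simulate_probe_array(
        base + 1, ann, truth, target="upf1", **array_kw
    )
    pol_ip1, pol_ctl1 = synthetic.simulate_probe_array(
        base + 2, ann, truth, target="polii", **array_kw
    )
    pol_ip2, pol_ctl2 = synthetic.simulate_probe_array(
        base + 3, ann, truth, target="polii", **array_kw
    )
    for name, df in [
        ("probes_upf1_ip.tsv", upf_ip),
        ("probes_upf1_control_1.tsv", upf_ctl1),
        ("probes_upf1_control_2.tsv", upf_ctl2),
        ("probes_polii_ip_1.tsv", pol_ip1),
        ("probes_polii_ip_2.tsv", pol_ip2),
        ("probes_polii_control_1.tsv", pol_ctl1),
        ("probes_polii_control_2.tsv", pol_ctl2),
    ]:
        anno.write_probe_table(df, run.record(name))

    cs = synthetic.child_seed(seed, "chipseq")
    ip_reads = synthetic.simulate_chipseq(
        cs, ann, truth, n_reads=cfg["chipseq_reads"],
        fragment_mean=cfg["fragment_mean"], fragment_sd=cfg["fragment_sd"],
        read_len=cfg["read_len"], target="polii",
    )
    input_reads = synthetic.simulate_chipseq(
        cs + 1, ann, None, n_reads=cfg["chipseq_reads"],
        fragment_mean=cfg["fragment_mean"], fragment_sd=cfg["fragment_sd"],
        read_len=cfg["read_len"],
    )
    chipseq.write_bed_intervals(ip_reads, run.record("chipseq_ip.bed"))
    chipseq.write_bed_intervals(input_reads, run.record("chipseq_input.bed"))

    fpkm = synthetic.simulate_expression(
        synthetic.child_seed(seed, "expression"), truth,
        n_replicates=cfg["n_replicates"], dispersion=cfg["fpkm_dispersion"],
    )
    fpkm.to_csv(run.record("fpkm.tsv"), sep="\t", index=False)
    de = synthetic.simulate_de_labels(
        synthetic.child_seed(seed, "de_labels"), truth,
        n_de=cfg["n_de"], frac_up=cfg["frac_up"],
        planted_overlap=cfg["planted_overlap"],
    )
    de.to_csv(run.record("de_labels.tsv"), sep="\t", index=False)
    truth.table.to_csv(run.record("ground_truth.tsv"), sep="\t", index=False)
    run.counts["genes_simulated"] = len(ann)
    run.counts["bound_genes"] = int(truth.table["bound"].sum())
    log.info("simulated %d genes (%d bound)", len(ann), run.counts["bound_genes"])


def _gene_signals(run: _Run) -> dict[str, chipchip.GeneSignalTable]:
    def mas5(name: str, origin: str) -> chipchip.GeneSignalTable:
        return chipchip.gene_signal_table(run.probe(name), origin=origin, assay=name)

    upf_ctl = chipchip.average_tables(
        list(chipchip.scale_to_common_median(
            mas5("probes_upf1_control_1.tsv", "control"),
            mas5("probes_upf1_control_2.tsv", "control"),
        ))
    )
    pol_ctl = chipchip.average_tables(
        list(chipchip.scale_to_common_median(
            mas5("probes_polii_control_1.tsv", "control"),
            mas5("probes_polii_control_2.tsv", "control"),
        ))
    )
    pol_ip = chipchip.average_tables(
        list(chipchip.scale_to_common_median(
            mas5("probes_polii_ip_1.tsv", "ip"),
            mas5("probes_polii_ip_2.tsv", "ip"),
        ))
    )
    upf_ip = mas5("probes_upf1_ip.tsv", "ip")
    return {
        "upf1": chipchip.normalize_by_control(upf_ip, upf_ctl),
        "polii": chipchip.normalize_by_control(pol_ip, pol_ctl),
    }


def stage_chip_signal(run: _Run) -> None:
    sig = _gene_signals(run)
    out = pd.DataFrame(
        {
            "gene_id": sig["upf1"].signal.index,
            "upf1_normalized": sig["upf1"].signal.values,
            "polii_normalized": sig["polii"].signal.reindex(
                sig["upf1"].signal.index
            ).values,
        }
    )
    out.to_csv(run.record("gene_signals.tsv"), sep="\t", index=False)
    run.counts["genes_with_signal"] = len(out)


def _normalized_probes(run: _Run) -> pd.DataFrame:
    return chipchip.probe_normalized_values(
        [run.probe("probes_upf1_ip.tsv")],
        [run.probe("probes_upf1_control_1.tsv"), run.probe("probes_upf1_control_2.tsv")],
    )


def stage_call_enriched(run: _Run) -> None:
    cfg = run.cfg["enrichment"]
    ann = run.annotation()
    normed = _normalized_probes(run)
    normed.to_csv(run.record("probes_upf1_normalized.tsv"), sep="\t", index=False)
    for suffix, cutoff in [("", cfg["p_cutoff"]), ("_strict", cfg["p_cutoff_strict"])]:
        calls = chipchip.call_enriched_genes(
            normed, ann, p_cutoff=cutoff,
            window_bp=cfg["window_bp"], maxgap_bp=cfg["maxgap_bp"],
        )
        df = chipchip.enriched_calls_frame(calls)
        df.to_csv(run.record(f"enriched_calls{suffix}.tsv"), sep="\t", index=False)
        run.counts[f"enriched_genes{suffix}"] = int(df["enriched"].sum())
    log.info(
        "enriched genes: %d (p<%g), %d (p<%g)",
        run.counts["enriched_genes"], cfg["p_cutoff"],
        run.counts["enriched_genes_strict"], cfg["p_cutoff_strict"],
    )


def stage_coverage(run: _Run) -> None:
    cfg = run.cfg["coverage"]
    ann = run.annotation()
    lengths = ann.chrom_lengths
    tracks = {}
    for role in ("ip", "input"):
        reads = chipseq.read_bed_intervals(run.path(f"chipseq_{role}.bed"))
        raw = chipseq.coverage_from_reads(reads, lengths, label=role)
        anno.write_bedgraph(raw, run.record(f"coverage_{role}_raw.bedgraph"))
        tracks[role] = chipseq.depth_normalize(raw, len(reads))
        anno.write_bedgraph(tracks[role], run.record(f"coverage_{role}_depthnorm.bedgraph"))
    normed = chipseq.input_normalize(
        tracks["ip"], tracks["input"], policy=cfg["policy"], epsilon=cfg["epsilon"]
    )
    anno.write_bedgraph(normed, run.record("coverage_ip_inputnorm.bedgraph"))


def stage_metagene(run: _Run) -> None:
    ann = run.annotation()
    normed = pd.read_csv(run.path("probes_upf1_normalized.tsv"), sep="\t")
    profile = metagene.build_probe_metagene(normed, ann)
    profile.to_frame().to_csv(run.record("metagene_probes.tsv"), sep="\t", index=False)
    track = anno.read_bedgraph(
        run.path("coverage_ip_inputnorm.bedgraph"), ann.chrom_lengths, normalized=True
    )
    prof2 = metagene.build_flank_body_metagene(track, ann)
    prof2.to_frame().to_csv(run.record("metagene_coverage.tsv"), sep="\t", index=False)


def stage_correlate(run: _Run) -> None:
    cfg = run.cfg["correlate"]
    sig = pd.read_csv(run.path("gene_signals.tsv"), sep="\t").set_index("gene_id")
    fpkm = pd.read_csv(run.path("fpkm.tsv"), sep="\t")
    expr = association.mean_log_fpkm(fpkm).set_index("gene_id")
    rho_pol, p_pol = association.spearman_correlation(
        sig["upf1_normalized"], sig["polii_normalized"]
    )
    rho_expr, p_expr = association.spearman_correlation(
        sig["upf1_normalized"], expr["log_fpkm"],
        top_expressed_fraction=cfg["top_expressed_fraction"],
    )
    out = pd.DataFrame(
        {
            "comparison": ["upf1_vs_polii", "upf1_vs_expression"],
            "rho": [rho_pol, rho_expr],
            "p_value": [p_pol, p_expr],
            "top_expressed_fraction": [np.nan, cfg["top_expressed_fraction"]],
        }
    )
    out.to_csv(run.record("correlations.tsv"), sep="\t", index=False)
    log.info("Spearman upf1~polii %.3f, upf1~expression %.3f", rho_pol, rho_expr)


def stage_classify(run: _Run) -> None:
    cfg = run.cfg["classify"]
    gain = run.cfg["simulate"]["probe_gain"]
    sig = pd.read_csv(run.path("gene_signals.tsv"), sep="\t").set_index("gene_id")
    # normalized array signal ~ 1 + gain*occupancy: subtract the unenriched
    # baseline so the ratio compares occupancy estimates
    occ_u = (sig["upf1_normalized"] - 1.0) / gain
    occ_p = (sig["polii_normalized"] - 1.0) / gain
    labels = association.classify_ratio_groups(
        occ_u, occ_p,
        theta_low=cfg["theta_low"], theta_high=cfg["theta_high"],
        min_signal=cfg["min_signal"],
    )
    labels.rename_axis("gene_id").reset_index().to_csv(
        run.record("ratio_groups.tsv"), sep="\t", index=False
    )
    counts = labels.value_counts().to_dict()
    run.counts.update({f"group_{k}": int(v) for k, v in counts.items()})
    log.info("ratio groups: %s", counts)


def stage_overlap(run: _Run) -> None:
    cfg = run.cfg["overlap"]
    ann = run.annotation()
    universe = ann.gene_ids
    calls = pd.read_csv(run.path("enriched_calls.tsv"), sep="\t")
    set_a = set(calls.loc[calls["enriched"], "gene_id"])
    de = pd.read_csv(run.path("de_labels.tsv"), sep="\t")
    set_b = set(de["gene_id"])
    res = association.overlap_permutation_test(
        set_a, universe, set_b, universe,
        reps=cfg["reps"], seed=run.cfg["seed"],
    )
    with open(run.record("overlap_test.json"), "w") as fh:
        json.dump(res.to_dict(), fh, indent=2)
    log.info("overlap k=%d p_perm=%.4g p_hyper=%.4g", res.k, res.p_permutation,
             res.p_hypergeometric)


STAGES = {
    "simulate": stage_simulate,
    "chip-signal": stage_chip_signal,
    "call-enriched": stage_call_enriched,
    "coverage": stage_coverage,
    "metagene": stage_metagene,
    "correlate": stage_correlate,
    "classify": stage_classify,
    "overlap-test": stage_overlap,
}

_STAGE_INPUTS = {
    "simulate": [],
    "chip-signal": ["probes_upf1_ip.tsv", "probes_polii_ip_1.tsv"],
    "call-enriched": ["annotation.gff3", "probes_upf1_ip.tsv"],
    "coverage": ["annotation.gff3", "chipseq_ip.bed", "chipseq_input.bed"],
    "metagene": ["annotation.gff3", "probes_upf1_normalized.tsv",
                 "coverage_ip_inputnorm.bedgraph"],
    "correlate": ["gene_signals.tsv", "fpkm.tsv"],
    "classify": ["gene_signals.tsv"],
    "overlap-test": ["annotation.gff3", "enriched_calls.tsv", "de_labels.tsv"],
}


def run_pipeline(
    config: dict, outdir: str, stages: list[str] | None = None
) -> dict:
    """Execute the requested stages in order and write the run manifest.

    Missing inputs for any requested stage are reported before any stage
    runs.  Returns the manifest dictionary.
    """
    if stages is None:
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    run = _Run(config, outdir)
    ordered = [s for s in STAGES if s in stages]
    produced = set()
    if "simulate" in ordered:
        produced.update(n for names in _STAGE_INPUTS.values() for n in names)
        produced.update(["probes_upf1_normalized.tsv", "gene_signals.tsv"])
    missing = []
    for s in ordered:
        for name in _STAGE_INPUTS[s]:
            if name not in produced and not os.path.exists(run.path(name)):
                missing.append(f"{s}: {name}")
        if s == "chip-signal":
            produced.add("gene_signals.tsv")
        if s == "call-enriched":
            produced.update(["probes_upf1_normalized.tsv", "enriched_calls.tsv"])
        if s == "coverage":
            produced.add("coverage_ip_inputnorm.bedgraph")
    if missing:
        raise FileNotFoundError(
            "missing inputs for requested stages: " + "; ".join(missing)
        )
    for s in ordered:
        log.info("stage %s", s)
        STAGES[s](run)
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": config["seed"],
        "stages": ordered,
        "artifacts": run.artifacts,
        "counts": run.counts,
    }
    with open(run.path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
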