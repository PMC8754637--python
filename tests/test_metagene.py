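import numpy as np
import pandas as pd
import pytest

import upfchip as u
from upfchip.metagene import PERCENT_BINS
from tests.conftest import make_probe_frame


class TestPercentPosition:
    gene_plus = u.Gene("gp", "chr1", 1000, 2025, "+")
    gene_minus = u.Gene("gm", "chr1", 1000, 2025, "-")

    def test_tss_anchor_is_zero_percent(self):
        assert u.probe_percent_position(1000, self.gene_plus) == 0.0

    def test_last_position_is_hundred_percent(self):
        # 5'-most base 24 bp upstream of the TES maps to 100%
        assert u.probe_percent_position(2000, self.gene_plus) == 100.0

    def test_minus_strand_flips_anchor(self):
        # footprint [2000, 2025): its 5'-most transcribed base is 2024 = TSS
        assert u.probe_percent_position(2000, self.gene_minus) == 0.0
        assert u.probe_percent_position(1000, self.gene_minus) == 100.0

    def test_out_of_range_marked(self):
        assert u.probe_percent_position(2001, self.gene_plus) is None
        assert u.probe_percent_position(999, self.gene_plus) is None

    def test_short_gene_rejected(self):
        with pytest.raises(ValueError):
            u.probe_percent_position(0, u.Gene("s", "chr1", 0, 20, "+"))


def _probe_values(ann, value=1.0, spacing=25):
    rows = []
    for g in ann:
        for pos in range(g.start, g.end - 25 + 1, spacing):
            rows.append([f"p{g.gene_id}_{pos}", g.chrom, pos, "+", 1.0, 1.0, g.gene_id])
    df = make_probe_frame(rows)
    df["value"] = value
    return df[["probe_id", "chrom", "position", "strand", "gene_id", "value"]]


class TestProbeMetagene:
    def test_flat_values_flat_profile(self, small_annotation):
        profile = u.build_probe_metagene(_probe_values(small_annotation), small_annotation)
        filled = profile.bins[profile.bin_counts > 0]
        assert np.max(np.abs(filled - 1.0)) < 1e-9

    def test_single_probe_lands_in_its_block(self):
        ann = u.GenomeAnnotation([u.Gene("g", "chr1", 0, 2025, "+")], {"chr1": 3000})
        df = _probe_values(ann).iloc[:0]
        # probe at 50%: u = 1000 = (L-25)/2
        row = pd.DataFrame(
            [["p0", "chr1", 1000, "+", "g", 2.0]],
            columns=["probe_id", "chrom", "position", "strand", "gene_id", "value"],
        )
        profile = u.build_probe_metagene(pd.concat([df, row]), ann)
        assert profile.bins[500] == 2.0
        assert profile.bin_counts[500] == 1
        assert profile.bin_counts.sum() == 1

    def test_strand_reflection_invariance(self, small_annotation):
        """Mirroring all genes and probes leaves the pooled profile unchanged."""
        rng = np.random.default_rng(3)
        probes = _probe_values(small_annotation)
        probes["value"] = rng.lognormal(0, 0.5, len(probes))
        profile = u.build_probe_metagene(probes, small_annotation)

        flip = {"+": "-", "-": "+"}
        L = {c: n for c, n in small_annotation.chrom_lengths.items()}
        mirrored_genes = [
            u.Gene(g.gene_id, g.chrom, L[g.chrom] - g.end, L[g.chrom] - g.start,
                   flip[g.strand], g.biotype)
            for g in small_annotation
        ]
        m_ann = u.GenomeAnnotation(mirrored_genes, small_annotation.chrom_lengths)
        m_probes = probes.copy()
        m_probes["position"] = m_probes["chrom"].map(L) - m_probes["position"] - 25
        m_profile = u.build_probe_metagene(m_probes, m_ann)
        np.testing.assert_allclose(profile.bins, m_profile.bins, equal_nan=True)
        np.testing.assert_array_equal(profile.bin_counts, m_profile.bin_counts)

    def test_no_in_range_probes_rejected(self, small_annotation):
        probes = _probe_values(small_annotation).iloc[:0]
        with pytest.raises(ValueError):
            u.build_probe_metagene(probes, small_annotation)


def brute_force_probe_metagene(probes, ann, probe_len=25):
    sums = np.zeros(PERCENT_BINS)
    counts = np.zeros(PERCENT_BINS, dtype=int)
    for _, row in probes.iterrows():
        if row.gene_id not in ann:
            continue
        g = ann[row.gene_id]
        pct = u.probe_percent_position(row.position, g, probe_len)
        if pct is None:
            continue
        b = min(int(pct // 0.1), PERCENT_BINS - 1)
        # float division can land on a bin edge; recompute exactly
        span = g.length - probe_len
        uu = row.position - g.start if g.strand == "+" else g.end - row.position - probe_len
        b = min((PERCENT_BINS * uu) // span, PERCENT_BINS - 1)
        sums[b] += row.value
        counts[b] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def brute_force_flank_body(track, ann, flank=1000, body_bins=1000):
    total = flank + body_bins + flank
    sums = np.zeros(total)
    counts = np.zeros(total, dtype=int)
    for g in ann:
        if g.length < body_bins // 10:
            continue
        v = track.values[g.chrom]
        n = len(v)
        sign = 1 if g.strand == "+" else -1
        tss, tes = g.tss, g.tes
        for j in range(flank):  # upstream, transcription direction
            p = tss - sign * (flank - j)
            if 0 <= p < n and not np.isnan(v[p]):
                sums[j] += v[p]
                counts[j] += 1
        for j in range(flank):  # downstream
            p = tes + sign * (j + 1)
            if 0 <= p < n and not np.isnan(v[p]):
                sums[flank + body_bins + j] += v[p]
                counts[flank + body_bins + j] += 1
        L = g.length
        body = v[g.start:g.end][::sign]
        for k in range(body_bins):
            lo, hi = k * L / body_bins, (k + 1) * L / body_bins
            wsum = vsum = 0.0
            for i in range(int(np.floor(lo)), min(int(np.ceil(hi)), L)):
                w = min(hi, i + 1) - max(lo, i)
                if w > 0 and not np.isnan(body[i]):
                    vsum += w * body[i]
                    wsum += w
            if wsum > 0:
                sums[flank + k] += vsum / wsum
                counts[flank + k] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


class TestFlankBodyMetagene:
    def test_uniform_track_gives_flat_profile(self, small_annotation, flat_track):
        profile = u.build_flank_body_metagene(flat_track, small_annotation)
        filled = profile.bins[profile.bin_counts > 0]
        assert np.max(np.abs(filled - 3.5)) < 1e-9

    def test_single_gene_step_profile(self):
        ann = u.GenomeAnnotation([u.Gene("g", "chr1", 2000, 4000, "+")], {"chr1": 8000})
        vals = np.ones(8000)
        vals[2000:4000] = 2.0
        track = u.CoverageTrack({"chr1": vals}, normalized=True)
        profile = u.build_flank_body_metagene(track, ann)
        np.testing.assert_allclose(profile.bins[:1000], 1.0)  # upstream flank
        np.testing.assert_allclose(profile.bins[1000:2000], 2.0)  # body
        np.testing.assert_allclose(profile.bins[2000:], 1.0)  # downstream flank

    def test_minus_strand_equals_mirrored_plus(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(0, 0.5, 9000)
        minus = u.GenomeAnnotation([u.Gene("g", "chr1", 3000, 5500, "-")], {"chr1": 9000})
        plus = u.GenomeAnnotation(
            [u.Gene("g", "chr1", 9000 - 5500, 9000 - 3000, "+")], {"chr1": 9000}
        )
        t_minus = u.CoverageTrack({"chr1": vals}, normalized=True)
        t_plus = u.CoverageTrack({"chr1": vals[::-1].copy()}, normalized=True)
        p_minus = u.build_flank_body_metagene(t_minus, minus)
        p_plus = u.build_flank_body_metagene(t_plus, plus)
        np.testing.assert_allclose(p_minus.bins, p_plus.bins, equal_nan=True, atol=1e-12)

    def test_clipped_flank_bases_excluded(self):
        ann = u.GenomeAnnotation([u.Gene("g", "chr1", 300, 1500, "+")], {"chr1": 1700})
        track = u.CoverageTrack({"chr1": np.ones(1700)}, normalized=True)
        profile = u.build_flank_body_metagene(track, ann)
        assert profile.bin_counts[:700].sum() == 0  # beyond chromosome start
        assert profile.bin_counts[700:1000].sum() == 300
        assert profile.bin_counts[2000:2200].sum() == 200
        assert profile.bin_counts[2200:].sum() == 0

    def test_empty_annotation_rejected(self, flat_track):
        with pytest.raises(ValueError):
            u.build_flank_body_metagene(
                u.CoverageTrack({"chr1": np.ones(10)}, normalized=True),
                u.GenomeAnnotation([], {"chr1": 10}),
            )


class TestBruteForceAgreement:
    def test_probe_metagene_matches_naive_loop(self, small_annotation):
        rng = np.random.default_rng(9)
        probes = _probe_values(small_annotation, spacing=40)
        probes["value"] = rng.lognormal(0, 0.7, len(probes))
        profile = u.build_probe_metagene(probes, small_annotation)
        means, counts = brute_force_probe_metagene(probes, small_annotation)
        np.testing.assert_array_equal(profile.bin_counts, counts)
        np.testing.assert_allclose(profile.bins, means, equal_nan=True, rtol=1e-12)

    def test_flank_body_matches_naive_loop(self, small_annotation):
        rng = np.random.default_rng(10)
        values = {}
        for c, n in small_annotation.chrom_lengths.items():
            v = rng.lognormal(0, 0.5, n)
            v[rng.random(n) < 0.05] = np.nan  # masked bases
            values[c] = v
        track = u.CoverageTrack(values, normalized=True)
        profile = u.build_flank_body_metagene(track, small_annotation, flank=200,
                                              body_bins=150)
        means, counts = brute_force_flank_body(track, small_annotation, flank=200,
                                               body_bins=150)
        np.testing.assert_array_equal(profile.bin_counts, counts)
        np.testing.assert_allclose(profile.bins, means, equal_nan=True, rtol=1e-9)
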