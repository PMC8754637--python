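import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import upfchip as u
from upfchip import chipchip as cc
from tests.conftest import make_probe_frame


class TestGeneSignal:
    def test_identical_pairs_give_the_common_value(self):
        # IM = mm, probe value log2(200-100); biweight of constants
        assert u.summarize_gene_signal([200] * 4, [100] * 4) == pytest.approx(100.0)

    def test_mm_above_pm_uses_half_pm_as_ideal_mismatch(self):
        assert u.summarize_gene_signal([200], [300]) == pytest.approx(100.0)

    def test_biweight_downweights_outlier_relative_to_mean(self):
        pm = np.array([200, 210, 190, 205, 200000.0])
        mm = np.array([100, 105, 95, 102, 100.0])
        signal = u.summarize_gene_signal(pm, mm)
        pv = np.log2(pm - mm)
        plain_mean = 2 ** pv.mean()
        consensus = 2 ** np.log2(pm[:4] - mm[:4]).mean()
        assert abs(signal - consensus) < abs(plain_mean - consensus)

    def test_zero_probes_rejected(self):
        with pytest.raises(ValueError):
            u.summarize_gene_signal([], [])

    @settings(max_examples=50, deadline=None)
    @given(
        pm=st.lists(st.floats(120, 1e5), min_size=1, max_size=12),
        factor=st.floats(1.0, 10.0),
    )
    def test_monotone_in_pm_above_mm(self, pm, factor):
        """Raising every PM (already above MM) never decreases the signal."""
        mm = [100.0] * len(pm)
        low = u.summarize_gene_signal(pm, mm)
        high = u.summarize_gene_signal([p * factor for p in pm], mm)
        assert high >= low - 1e-9


def _table(values, origin="ip"):
    return cc.GeneSignalTable(pd.Series(values, dtype=float), origin=origin)


class TestTableOps:
    def test_median_scaling_forced_arithmetic(self):
        a = _table({"g1": 10, "g2": 10, "g3": 10})
        b = _table({"g1": 20, "g2": 20, "g3": 20})
        sa, sb = u.scale_to_common_median(a, b)
        assert sa.signal.median() == sb.signal.median() == pytest.approx(15.0)
        np.testing.assert_allclose(sa.signal, 15.0)

    def test_median_scaling_identity_for_identical_tables(self):
        a = _table({"g1": 3, "g2": 5})
        sa, sb = u.scale_to_common_median(a, a)
        np.testing.assert_allclose(sa.signal, a.signal)
        np.testing.assert_allclose(sb.signal, a.signal)

    def test_median_scaling_property_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            genes = [f"g{i}" for i in range(11)]
            a = _table(dict(zip(genes, rng.lognormal(0, 1, 11))))
            b = _table(dict(zip(genes, rng.lognormal(1, 1, 11))))
            sa, sb = u.scale_to_common_median(a, b)
            assert sa.signal.median() == pytest.approx(sb.signal.median())

    def test_average_tables(self):
        a = _table({"g1": 1.0})
        b = _table({"g1": 3.0})
        assert u.average_tables([a, b]).signal["g1"] == 2.0
        np.testing.assert_allclose(u.average_tables([a]).signal, a.signal)
        np.testing.assert_allclose(u.average_tables([b, b, b]).signal, b.signal)

    def test_normalize_identity_and_example(self):
        ip = _table({"g1": 4.0, "g2": 6.0})
        np.testing.assert_allclose(
            u.normalize_by_control(ip, _table(ip.signal.to_dict(), "control")).signal,
            1.0,
        )
        out = u.normalize_by_control(_table({"g1": 4.0}), _table({"g1": 2.0}, "control"))
        assert out.signal["g1"] == 2.0
        assert out.origin == "normalized"

    def test_normalize_scale_invariance(self):
        ip = _table({"g1": 4.0, "g2": 6.0})
        ctl = _table({"g1": 2.0, "g2": 3.0}, "control")
        base = u.normalize_by_control(ip, ctl).signal
        scaled = u.normalize_by_control(
            _table((ip.signal * 7).to_dict()), _table((ctl.signal * 7).to_dict(), "control")
        ).signal
        np.testing.assert_allclose(base, scaled)

    def test_mismatched_gene_sets_error_names_difference(self):
        with pytest.raises(ValueError, match="g2"):
            u.normalize_by_control(
                _table({"g1": 1.0, "g2": 1.0}), _table({"g1": 1.0}, "control")
            )

    def test_nonpositive_control_gene_dropped(self):
        out = u.normalize_by_control(
            _table({"g1": 4.0, "g2": 4.0}), _table({"g1": 2.0, "g2": 0.0}, "control")
        )
        assert list(out.signal.index) == ["g1"]


class TestProbeNormalization:
    def _arrays(self):
        base = make_probe_frame(
            [["p1", "chr1", 0, "+", 200.0, 100.0, "g1"],
             ["p2", "chr1", 25, "+", 300.0, 150.0, "g1"]]
        )
        ctl = base.copy()
        ctl["pm"] = ctl["mm"]  # ratio 1 everywhere
        return base, ctl

    def test_ip_ratio_over_control_mean(self):
        ip, ctl = self._arrays()
        out = u.probe_normalized_values([ip], [ctl])
        np.testing.assert_allclose(out["value"], 2.0)

    def test_ip_equal_to_control_gives_unity(self):
        ip, _ = self._arrays()
        out = u.probe_normalized_values([ip], [ip, ip])
        np.testing.assert_allclose(out["value"], 1.0)

    def test_two_identical_ip_arrays_average_to_either(self):
        ip, ctl = self._arrays()
        one = u.probe_normalized_values([ip], [ctl])
        two = u.probe_normalized_values([ip, ip], [ctl])
        np.testing.assert_allclose(one["value"], two["value"])

    def test_probe_set_mismatch_rejected(self):
        ip, ctl = self._arrays()
        with pytest.raises(ValueError, match="probe sets"):
            u.probe_normalized_values([ip], [ctl.iloc[:1]])


def _background_probes(rng, ann, spacing=25):
    rows = []
    for chrom, clen in ann.chrom_lengths.items():
        for pos in range(0, clen - 25, spacing):
            rows.append([f"p_{chrom}_{pos}", chrom, pos, "+",
                         float(np.exp(rng.normal(0, 0.3))), 0.0, "x"])
    df = make_probe_frame(rows)
    df["value"] = df["pm"]
    return df[["probe_id", "chrom", "position", "strand", "gene_id", "value"]]


class TestEnrichedCalling:
    def test_null_input_rarely_calls_genes(self, small_annotation):
        """Background-only probes: false-positive gene calls stay rare."""
        probes = _background_probes(np.random.default_rng(5), small_annotation)
        calls = u.call_enriched_genes(probes, small_annotation, p_cutoff=1e-3)
        n_called = sum(c.enriched for c in calls)
        assert n_called == 0

    def test_strongly_elevated_gene_fully_covered(self, small_annotation):
        probes = _background_probes(np.random.default_rng(6), small_annotation)
        gene = small_annotation.genes[0]
        inside = (probes["chrom"] == gene.chrom) & \
                 (probes["position"] >= gene.start) & (probes["position"] < gene.end)
        probes.loc[inside, "value"] *= 10.0
        calls = {c.gene_id: c for c in
                 u.call_enriched_genes(probes, small_annotation, p_cutoff=1e-3)}
        call = calls[gene.gene_id]
        assert call.enriched and call.fraction_significant == pytest.approx(1.0)
        assert call.enrichment_score > 5.0

    def test_forty_percent_elevation_is_not_enriched(self):
        # long gene so the +-150 bp window bleed stays small vs gene length
        ann = u.GenomeAnnotation(
            [u.Gene("g", "chr1", 2000, 8000, "+")], {"chr1": 12000}
        )
        probes = _background_probes(np.random.default_rng(7), ann)
        cut = 2000 + int(0.4 * 6000)
        inside = (probes["position"] >= 2000) & (probes["position"] < cut)
        probes.loc[inside, "value"] *= 10.0
        call = u.call_enriched_genes(probes, ann, p_cutoff=1e-3)[0]
        assert not call.enriched
        assert 0.0 < call.fraction_significant < 0.5

    def test_stricter_cutoff_calls_are_subset(self, small_annotation, small_truth):
        ip, c1 = u.simulate_probe_array(55, small_annotation, small_truth, spacing=25)
        _, c2 = u.simulate_probe_array(56, small_annotation, small_truth, spacing=25)
        normed = u.probe_normalized_values([ip], [c1, c2])
        loose = {c.gene_id for c in
                 u.call_enriched_genes(normed, small_annotation, 1e-3) if c.enriched}
        strict = {c.gene_id for c in
                  u.call_enriched_genes(normed, small_annotation, 1e-4) if c.enriched}
        assert strict <= loose

    def test_empty_probe_set_rejected(self, small_annotation):
        with pytest.raises(ValueError):
            u.call_enriched_genes(
                pd.DataFrame(columns=["probe_id", "chrom", "position", "value"]),
                small_annotation,
            )

    def test_degenerate_constant_scores_rejected(self, small_annotation):
        df = _background_probes(np.random.default_rng(8), small_annotation)
        df["value"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            u.call_enriched_genes(df, small_annotation)
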