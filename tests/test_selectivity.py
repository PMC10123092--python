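"""Binding ratios, decile grouping, category comparisons, and ΔTE."""

import numpy as np
import pytest
from scipy import stats as sps

from riboselect.selectivity import (
    GeneBindingStat,
    TEResult,
    binding_ratio_per_gene,
    compare_binding_by_uorf_category,
    correlate_binding_vs_dte,
    decile_groups,
    translation_efficiency,
)
from riboselect.synthetic import (
    SimConfig,
    simulate_footprints,
    simulate_rna_counts,
    simulate_transcriptome,
)
from riboselect.tracks import FootprintTrack, Interval, TranscriptModel
from riboselect.uorfs import annotate_uorfs, categorize_transcripts


def _stats(values):
    return [GeneBindingStat(gene_id=f"g{i:05d}", binding_ratio=float(v), coverage=100)
            for i, v in enumerate(values)]


class TestBindingRatio:
    def test_identical_tracks_equal_depth_unit_ratio(self):
        t = TranscriptModel("T1", Interval(0, 100), Interval(100, 400),
                            Interval(400, 400))
        vec = np.ones(400, dtype=int)
        sel = FootprintTrack("s", "40S", "selective", {"T1": vec})
        tot = FootprintTrack("t", "40S", "total", {"T1": vec.copy()})
        (st,) = binding_ratio_per_gene(sel, tot, [t], pseudocount=0.0)
        assert st.binding_ratio == pytest.approx(1.0)

    def test_zero_selective_small_positive_with_pseudocount(self):
        t = TranscriptModel("T1", Interval(0, 100), Interval(100, 400),
                            Interval(400, 400))
        sel = FootprintTrack("s", "40S", "selective", {"T1": np.zeros(400, int)})
        tot = FootprintTrack("t", "40S", "total", {"T1": np.ones(400, int)})
        (st,) = binding_ratio_per_gene(sel, tot, [t], pseudocount=0.5)
        assert 0 < st.binding_ratio < 1

    def test_two_capture_classes_separate(self):
        """Genes simulated at 0.05 vs 0.5 40S capture form two ratio modes."""
        cfg = SimConfig(n_transcripts=200, ip_utr_base_rate=0.05,
                        ip_utr_uorf_rate=0.5, seed=17)
        tx, truth = simulate_transcriptome(cfg)
        libs = simulate_footprints(tx, truth, "control", cfg)
        stats_list = binding_ratio_per_gene(libs["selective_40s"],
                                            libs["total_40s"], tx)
        by_gene = {s.gene_id: s.binding_ratio for s in stats_list}
        hi = [by_gene[t.transcript_id] for t in tx
              if truth[t.transcript_id].ip_utr_rate == 0.5]
        lo = [by_gene[t.transcript_id] for t in tx
              if truth[t.transcript_id].ip_utr_rate == 0.05]
        assert len(hi) > 20 and len(lo) > 20
        assert min(hi) > max(lo)  # fully separated at this depth
        # recovered class ratio tracks the configured 10x capture contrast
        assert np.mean(hi) / np.mean(lo) == pytest.approx(10.0, rel=0.25)


class TestDecileGroups:
    def test_published_detected_gene_count_gives_470(self):
        df = decile_groups(_stats(np.linspace(0, 1, 4707)), fraction=0.1)
        assert (df["decile"] == "top10").sum() == 470
        assert (df["decile"] == "bottom10").sum() == 470

    def test_small_n_floor(self):
        df = decile_groups(_stats(range(10)), fraction=0.1)
        assert (df["decile"] == "top10").sum() == 1

    def test_ties_resolved_deterministically(self):
        df1 = decile_groups(_stats(np.ones(50)), fraction=0.1)
        df2 = decile_groups(_stats(np.ones(50)), fraction=0.1)
        assert (df1["decile"] == "top10").sum() == 5
        assert df1.equals(df2)

    def test_partition_and_symmetry(self):
        df = decile_groups(_stats(np.random.default_rng(0).random(333)), fraction=0.2)
        counts = df["decile"].value_counts()
        assert counts.sum() == 333
        assert counts["top10"] == counts["bottom10"] == 66

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            decile_groups(_stats(range(5)), fraction=0.1)


class TestCategoryComparison:
    def test_constant_groups_zero_statistic(self):
        stats_list = _stats(np.ones(40))
        cats = {f"g{i:05d}": ("a" if i < 20 else "b") for i in range(40)}
        res = compare_binding_by_uorf_category(stats_list, cats)
        assert res.statistic == 0.0
        assert (res.pairwise["z"] == 0).all()

    def test_dunn_small_example_against_hand_computation(self):
        # groups [1,2,3] vs [4,5,6]: mean ranks 2 and 5, no ties
        stats_list = _stats([1, 2, 3, 4, 5, 6])
        cats = {f"g{i:05d}": ("a" if i < 3 else "b") for i in range(6)}
        res = compare_binding_by_uorf_category(stats_list, cats)
        se = np.sqrt((6 * 7 / 12) * (1 / 3 + 1 / 3))
        z_expect = (2 - 5) / se
        assert res.pairwise["z"].iloc[0] == pytest.approx(z_expect)
        assert res.pairwise["p_adjusted"].iloc[0] == pytest.approx(
            min(1, 2 * sps.norm.sf(abs(z_expect))), rel=1e-9)

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            compare_binding_by_uorf_category(_stats([1, 2]), {})

    def test_translated_uorf_group_detected_with_higher_capture(self):
        """2x capture on translated-uORF genes is called significant."""
        cfg = SimConfig(n_transcripts=300, ip_utr_base_rate=0.2,
                        ip_utr_uorf_rate=0.4, seed=23)
        tx, truth = simulate_transcriptome(cfg)
        libs = simulate_footprints(tx, truth, "control", cfg)
        annotate_uorfs(tx)
        cats = categorize_transcripts(tx, libs["total_80s"])
        stats_list = binding_ratio_per_gene(libs["selective_40s"],
                                            libs["total_40s"], tx)
        res = compare_binding_by_uorf_category(stats_list, cats)
        assert res.p_value < 1e-6
        pair = res.pairwise.set_index(["group_a", "group_b"])
        key = ("uorf_translated", "no_uorf") \
            if ("uorf_translated", "no_uorf") in pair.index else ("no_uorf", "uorf_translated")
        assert pair.loc[key, "p_adjusted"] < 1e-6


class TestTranslationEfficiency:
    def _dataset(self, n=40, seed=31, **kw):
        cfg = SimConfig(n_transcripts=n, seed=seed, **kw)
        tx, truth = simulate_transcriptome(cfg)
        libs = {c: simulate_footprints(tx, truth, c, cfg)
                for c in ("control", "knockdown")}
        rna = {c: simulate_rna_counts(tx, c, cfg) for c in ("control", "knockdown")}
        return cfg, tx, truth, libs, rna

    def test_identical_conditions_zero_dte(self, small_sim):
        _, tx, _, libs, rna = small_sim
        res = translation_efficiency(
            {"control": libs["control"]["total_80s"],
             "knockdown": libs["control"]["total_80s"]},
            {"control": rna["control"], "knockdown": rna["control"]}, tx)
        assert all(r.log2_dte == 0.0 for r in res)

    def test_halved_footprints_give_minus_one_when_depth_fixed(self):
        t = TranscriptModel("T1", Interval(0, 10), Interval(10, 310),
                            Interval(310, 310))
        t2 = TranscriptModel("T2", Interval(0, 10), Interval(10, 310),
                             Interval(310, 310))
        full = np.full(310, 8, dtype=int)
        half = np.full(310, 4, dtype=int)
        # T1 halves, T2 unchanged; depth normalization uses both genes
        ctrl = FootprintTrack("c", "80S", "total", {"T1": full, "T2": full})
        trt = FootprintTrack("k", "80S", "total", {"T1": half, "T2": full + 4})
        # treated library size equals control (4+12 == 8+8)
        rna = {"control": {"T1": 1000, "T2": 1000},
               "knockdown": {"T1": 1000, "T2": 1000}}
        res = translation_efficiency({"control": ctrl, "knockdown": trt},
                                     rna, [t, t2], pseudocount=0.0)
        by = {r.gene_id: r.log2_dte for r in res}
        assert by["T1"] == pytest.approx(-1.0)

    def test_depth_invariance(self, small_sim):
        _, tx, _, libs, rna = small_sim
        base = translation_efficiency(
            {c: libs[c]["total_80s"] for c in ("control", "knockdown")}, rna, tx)
        scaled_counts = {tid: v * 7 for tid, v in
                         libs["control"]["total_80s"].counts.items()}
        scaled = FootprintTrack("c7", "80S", "total", scaled_counts)
        res = translation_efficiency(
            {"control": scaled, "knockdown": libs["knockdown"]["total_80s"]}, rna, tx)
        for a, b in zip(base, res):
            assert b.log2_dte == pytest.approx(a.log2_dte, abs=1e-9)

    def test_missing_rna_skipped_with_warning(self, small_sim):
        _, tx, _, libs, rna = small_sim
        rna_missing = {c: {k: v for k, v in rna[c].items()
                           if k != tx[0].transcript_id} for c in rna}
        with pytest.warns(UserWarning, match="skipped"):
            res = translation_efficiency(
                {c: libs[c]["total_80s"] for c in ("control", "knockdown")},
                rna_missing, tx)
        assert len(res) == len(tx) - 1

    def test_uorf_genes_drop_more_than_uorf_free_genes(self):
        """Knockdown shifts initiation into uORFs, lowering mORF TE only
        on uORF-containing genes."""
        cfg, tx, truth, libs, rna = self._dataset(n=200, seed=37,
                                                  depletion_leak_shift=2.5)
        res = translation_efficiency(
            {c: libs[c]["total_80s"] for c in ("control", "knockdown")}, rna, tx)
        by = {r.gene_id: r.log2_dte for r in res}
        with_u = [by[t.transcript_id] for t in tx
                  if any(p > 0 for p in truth[t.transcript_id].uorf_init_probs)]
        without = [by[t.transcript_id] for t in tx
                   if not any(p > 0 for p in truth[t.transcript_id].uorf_init_probs)]
        assert np.mean(with_u) < np.mean(without) - 0.1


class TestCorrelation:
    def _te(self, gene_ids, dte):
        return [TEResult(g, 1.0, 2 ** d, float(d)) for g, d in zip(gene_ids, dte)]

    def test_perfect_monotone_coupling(self):
        s = _stats(np.linspace(0.1, 2.0, 20))
        te = self._te([x.gene_id for x in s], -np.linspace(0.1, 2.0, 20))
        res = correlate_binding_vs_dte(s, te)
        assert res.rho == pytest.approx(-1.0)
        te_up = self._te([x.gene_id for x in s], np.linspace(0.1, 2.0, 20))
        assert correlate_binding_vs_dte(s, te_up).rho == pytest.approx(1.0)

    def test_too_few_shared_genes_rejected(self):
        s = _stats([1, 2])
        te = self._te([x.gene_id for x in s], [0, 0])
        with pytest.raises(ValueError, match="3 genes"):
            correlate_binding_vs_dte(s, te)

    def test_coupled_simulation_negative_uncoupled_null_small(self):
        # coupling: high 40S capture on the same genes whose TE drops
        cfg = SimConfig(n_transcripts=400, ip_utr_uorf_rate=0.5, seed=41)
        tx, truth = simulate_transcriptome(cfg)
        libs = {c: simulate_footprints(tx, truth, c, cfg)
                for c in ("control", "knockdown")}
        rna = {c: simulate_rna_counts(tx, c, cfg) for c in ("control", "knockdown")}
        s = binding_ratio_per_gene(libs["control"]["selective_40s"],
                                   libs["control"]["total_40s"], tx)
        te = translation_efficiency(
            {c: libs[c]["total_80s"] for c in ("control", "knockdown")}, rna, tx)
        assert correlate_binding_vs_dte(s, te).rho < -0.3
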