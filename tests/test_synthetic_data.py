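import numpy as np
import pandas as pd
import pytest

from acetdiff.genome_io import GenomeSpec
from acetdiff.motif_enrichment import default_motif_library, pwm_scan
from acetdiff.synthetic_data import (
    NULL_CLASS,
    REGION_CLASSES,
    SimConfig,
    build_truth,
    plant_motifs,
    simulate_atac_peaks,
    simulate_expression,
    simulate_fragments,
    simulate_genome_sequence,
)


def tiny_config(**kw):
    defaults = dict(
        seed=7,
        genome=GenomeSpec((("chr1", 400_000), ("chr2", 400_000))),
        n_enhancers={c: 5 for c in REGION_CLASSES} | {NULL_CLASS: 30},
        n_genes=20,
        n_de_genes=10,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestTruthLayout:
    def test_no_two_elements_overlap(self):
        truth = build_truth(tiny_config())
        spans = [
            (r.chrom, r.start, r.end) for r in truth.enhancers.itertuples()
        ] + [
            (g.chrom, g.tss - 2000, g.tss + 2000) for g in truth.genes.itertuples()
        ]
        by_chrom = {}
        for chrom, s, e in spans:
            by_chrom.setdefault(chrom, []).append((s, e))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_class_counts_match_config(self):
        cfg = tiny_config()
        truth = build_truth(cfg)
        counts = truth.enhancers["region_class"].value_counts().to_dict()
        for cls, n in cfg.n_enhancers.items():
            assert counts.get(cls, 0) == n

    def test_fold_changes_and_directions_consistent(self):
        truth = build_truth(tiny_config())
        for r in truth.enhancers.itertuples():
            assert r.true_log2fc == pytest.approx(np.log2(r.fold))
            if r.region_class in ("both_up", "atac_up_only"):
                assert r.atac_direction == "up"
            elif r.region_class in ("both_down", "atac_down_only"):
                assert r.atac_direction == "down"
            else:
                assert r.atac_direction == "none"

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_truth(tiny_config(genome=GenomeSpec((("chr1", 50_000),))))

    def test_coupled_fraction_links_expression_and_promoter(self):
        truth = build_truth(tiny_config(coupled_fraction=1.0))
        de = truth.genes[truth.genes["expression_log2fc"] != 0]
        assert len(de) == 10
        assert (np.sign(de["promoter_log2fc"]) == np.sign(de["expression_log2fc"])).all()
        null = truth.genes[truth.genes["expression_log2fc"] == 0]
        assert (null["promoter_log2fc"] == 0).all()

    def test_zero_coupling_leaves_promoters_flat(self):
        truth = build_truth(tiny_config(coupled_fraction=0.0))
        assert (truth.genes["promoter_log2fc"] == 0).all()


class TestSequence:
    def test_deterministic_for_fixed_seed(self):
        cfg = tiny_config()
        assert simulate_genome_sequence(cfg) == simulate_genome_sequence(cfg)

    def test_gc_content_near_target(self):
        cfg = tiny_config(gc_content=0.42)
        seq = simulate_genome_sequence(cfg)["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.42) < 0.01

    def test_gc_one_yields_only_strong_bases(self):
        cfg = tiny_config(gc_content=1.0)
        seq = simulate_genome_sequence(cfg)["chr1"]
        assert set(seq) <= {"G", "C"}


class TestPlantMotifs:
    def test_instances_land_at_enhancer_centres(self):
        cfg = tiny_config()
        truth = build_truth(cfg)
        lib = default_motif_library()
        seqs = plant_motifs(simulate_genome_sequence(cfg), truth, lib, cfg)
        ap1 = next(m for m in lib if m.motif_id == "AP1")
        planted = truth.enhancers[truth.enhancers["region_class"] == "both_up"]
        found = 0
        for r in planted.itertuples():
            c = (r.start + r.end) // 2
            window = seqs[r.chrom][c - 20 : c + 20]
            if pwm_scan(window, ap1, score_fraction=0.8):
                found += 1
        assert found >= 0.6 * len(planted)  # sampled instances mostly scoreable

    def test_null_enhancers_untouched(self):
        cfg = tiny_config()
        truth = build_truth(cfg)
        raw = simulate_genome_sequence(cfg)
        planted = plant_motifs(raw, truth, default_motif_library(), cfg)
        nulls = truth.enhancers[truth.enhancers["region_class"] == NULL_CLASS]
        for r in nulls.itertuples():
            assert planted[r.chrom][r.start : r.end] == raw[r.chrom][r.start : r.end]

    def test_motif_longer_than_enhancer_rejected(self):
        cfg = tiny_config(enhancer_width=8)
        truth = build_truth(cfg)
        with pytest.raises(ValueError, match="longer than enhancer"):
            plant_motifs(
                simulate_genome_sequence(cfg), truth, default_motif_library(), cfg
            )


class TestFragments:
    def test_poisson_limit_mean(self):
        cfg = SimConfig(
            seed=3,
            genome=GenomeSpec((("chr1", 5_000_000),)),
            n_enhancers={NULL_CLASS: 0},
            n_genes=0,
            n_de_genes=0,
            dispersion=0.0,
            background_rate=10.0,
        )
        truth = build_truth(cfg)
        frags = simulate_fragments(cfg, truth)
        counts = len(frags["control_1"]) / 10_000  # 10,000 bins
        assert 9.8 <= counts <= 10.2

    def test_unit_fold_change_keeps_conditions_identical_in_law(self):
        cfg = tiny_config(
            fold_change={c: 1.0 for c in list(REGION_CLASSES) + [NULL_CLASS]},
            n_genes=0,
            n_de_genes=0,
        )
        truth = build_truth(cfg)
        frags = simulate_fragments(cfg, truth)
        n_ctrl = np.mean([len(frags[f"control_{i+1}"]) for i in range(3)])
        n_case = np.mean([len(frags[f"case_{i+1}"]) for i in range(3)])
        assert abs(n_case / n_ctrl - 1) < 0.05

    def test_library_size_factor_scales_totals(self):
        cfg = tiny_config(library_size_factors=(1.0, 1.0, 1.0, 2.0, 1.0, 1.0))
        truth = build_truth(cfg)
        frags = simulate_fragments(cfg, truth)
        ratio = len(frags["case_1"]) / len(frags["case_2"])
        assert abs(ratio - 2.0) < 0.1

    def test_fragments_have_fixed_length_inside_genome(self):
        cfg = tiny_config()
        truth = build_truth(cfg)
        frags = simulate_fragments(cfg, truth)["control_1"]
        assert ((frags["end"] - frags["start"]) <= 150).all()
        assert (frags["start"] >= 0).all()
        for chrom, sub in frags.groupby("chrom"):
            assert (sub["end"] <= cfg.genome.lengths[chrom]).all()

    def test_planted_fold_change_visible_in_expected_counts(self):
        cfg = tiny_config()
        truth = build_truth(cfg)
        frags = simulate_fragments(cfg, truth)
        gained = truth.enhancers[truth.enhancers["region_class"] == "both_up"]
        def mean_count(samples, r):
            tot = 0
            for s in samples:
                f = frags[s]
                mid = (f["start"] + f["end"]) // 2
                tot += (
                    (f["chrom"] == r.chrom) & (mid >= r.start) & (mid < r.end)
                ).sum()
            return tot / len(samples)
        ctrl = sum(mean_count([f"control_{i+1}" for i in range(3)], r)
                   for r in gained.itertuples())
        case = sum(mean_count([f"case_{i+1}" for i in range(3)], r)
                   for r in gained.itertuples())
        # elevation 50, fold 4, background 10 over ~2.2 bins
        assert case / ctrl > 2.0


class TestAtacPeaks:
    def test_peak_equals_enhancer_with_centred_summit(self):
        cfg = tiny_config()
        truth = build_truth(cfg)
        up, down = simulate_atac_peaks(truth)
        expect_up = truth.enhancers[
            truth.enhancers["region_class"].isin(["both_up", "atac_up_only"])
        ]
        assert len(up) == len(expect_up)
        for r in up.itertuples():
            assert r.summit_start == (r.start + r.end) // 2 - 100
            assert r.summit_end - r.summit_start == 200

    def test_acet_only_classes_emit_no_peaks(self):
        cfg = tiny_config()
        truth = build_truth(cfg)
        up, down = simulate_atac_peaks(truth)
        emitted = set(up["name"]) | set(down["name"])
        assert "acet_up_only" not in emitted and "acet_down_only" not in emitted

    def test_no_enhancers_gives_empty_tables(self):
        cfg = tiny_config(
            n_enhancers={c: 0 for c in list(REGION_CLASSES) + [NULL_CLASS]}
        )
        truth = build_truth(cfg)
        up, down = simulate_atac_peaks(truth)
        assert len(up) == 0 and len(down) == 0


class TestExpression:
    def test_deterministic(self):
        cfg = tiny_config()
        truth = build_truth(cfg)
        a = simulate_expression(cfg, truth)
        b = simulate_expression(cfg, truth)
        pd.testing.assert_frame_equal(a, b)

    def test_design_is_three_vs_five(self):
        cfg = tiny_config()
        truth = build_truth(cfg)
        table = simulate_expression(cfg, truth)
        assert sum(c.startswith("rna_control") for c in table.columns) == 3
        assert sum(c.startswith("rna_case") for c in table.columns) == 5

    def test_coupled_gene_counts_shift_with_sign(self):
        cfg = tiny_config(coupled_fraction=1.0, expression_lfc=2.0)
        truth = build_truth(cfg)
        table = simulate_expression(cfg, truth)
        ctrl = [c for c in table.columns if "control" in c]
        case = [c for c in table.columns if "case" in c]
        up = truth.genes[truth.genes["expression_log2fc"] > 0]["gene_id"]
        ratio = (table.loc[up, case].mean(axis=1) + 1) / (
            table.loc[up, ctrl].mean(axis=1) + 1
        )
        assert (ratio > 1.5).mean() > 0.8
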