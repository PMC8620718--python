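"""Reference simulation studies exercising the pipeline on known truth.

These routines back both the test suite and the reproduction script: each
one regenerates its inputs from a seed, runs the relevant slice of the
pipeline, and reports the measured operating characteristics (null
calibration, region recovery, concordance, motif recovery).
"""

from __future__ import annotations

import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning_signal, differential, expression_concordance, pipeline
from .genome_io import GenomeSpec, make_bin_grid
from .pipeline import PipelineConfig, region_recovery_metrics
from .synthetic_data import (
    NULL_CLASS,
    REGION_CLASSES,
    SimConfig,
    _nb_draw,
    build_truth,
    simulate_expression,
    simulate_fragments,
    write_dataset,
)


def null_calibration(
    seed: int,
    n_features: int = 10_000,
    n_control: int = 3,
    n_case: int = 3,
    dispersion: float = 0.05,
    mean: float = 100.0,
) -> dict:
    """Null NB simulation; measures raw p-value uniformity of the Wald test.

    Returns the fraction of p-values below 0.05 and the largest absolute
    deviation of the empirical p-value CDF from uniform at the deciles.
    """
    rng = np.random.default_rng([seed, 11])
    mu = np.full(n_features, float(mean))
    cols = {}
    conditions = {}
    for i in range(n_control):
        cols[f"control_{i+1}"] = _nb_draw(rng, mu, dispersion)
        conditions[f"control_{i+1}"] = "control"
    for i in range(n_case):
        cols[f"case_{i+1}"] = _nb_draw(rng, mu, dispersion)
        conditions[f"case_{i+1}"] = "case"
    res = differential.nb_wald_test(pd.DataFrame(cols), conditions)
    p = res["p"].to_numpy()
    deciles = np.arange(0.1, 1.0, 0.1)
    dev = max(abs(float((p < d).mean()) - d) for d in deciles)
    return {
        "frac_p_below_05": float((p < 0.05).mean()),
        "max_decile_deviation": dev,
        "n": n_features,
    }


def region_recovery_config(seed: int) -> SimConfig:
    """Study conditions for region recovery: 200 four-fold enhancers (100
    gained, 100 lost; low side at 50 counts/bin) among 20,000 bins with a
    2,000-peak stable backdrop, 3 vs 3."""
    n_enh = {c: 0 for c in REGION_CLASSES}
    n_enh.update({"acet_up_only": 100, "acet_down_only": 100, NULL_CLASS: 2000})
    return SimConfig(
        seed=seed,
        genome=GenomeSpec((("chr1", 5_000_000), ("chr2", 5_000_000))),
        n_enhancers=n_enh,
        n_genes=0,
        n_de_genes=0,
    )


def region_recovery(seed: int, q_threshold: float = 0.05) -> dict:
    """Full count->normalize->test->merge chain against planted truth."""
    cfg = region_recovery_config(seed)
    truth = build_truth(cfg)
    grid = make_bin_grid(cfg.genome, cfg.bin_width)
    fragments = simulate_fragments(cfg, truth)
    raw = binning_signal.bin_count_matrix(fragments, grid, cfg.conditions)
    normed, _ = binning_signal.normalize_counts(raw)
    features, values = differential.drop_all_zero(normed.features, normed.values)
    res = differential.nb_wald_test(values, cfg.conditions)
    res = differential.finalize_results(res, q_threshold)
    bin_diff = pd.concat(
        [features.reset_index(drop=True), res.reset_index(drop=True)], axis=1
    )
    regions = differential.merge_significant_bins(bin_diff, q_threshold)
    planted = [
        (r.chrom, r.start, r.end, "up" if r.fold > 1 else "down")
        for r in truth.enhancers.itertuples()
        if r.fold != 1.0
    ]
    return region_recovery_metrics(regions, planted)


def concordance_recovery(seed: int, coupled_fraction: float = 1.0) -> dict:
    """Coupled expression/promoter simulation; measures concordance recovery."""
    cfg = SimConfig(seed=seed, coupled_fraction=coupled_fraction)
    truth = build_truth(cfg)
    fragments = simulate_fragments(cfg, truth)
    from .genome_io import GeneModel

    genes = [
        GeneModel(g.gene_id, g.chrom, g.strand, int(g.tss))
        for g in truth.genes.itertuples()
    ]
    prom = differential.promoter_differential(
        fragments, genes, cfg.genome, cfg.conditions, flank=cfg.promoter_flank
    )
    expr = simulate_expression(cfg, truth)
    de = expression_concordance.de_genes(expr, cfg.rna_conditions)
    _, summary = expression_concordance.concordance(de, prom)
    return summary


def motif_recovery_config(seed: int) -> SimConfig:
    """Study conditions for motif recovery: 200 enhancers in each of the six
    overlap classes plus 1,000 stable peaks, default motif plantings."""
    n_enh = {c: 200 for c in REGION_CLASSES}
    n_enh[NULL_CLASS] = 1000
    return SimConfig(
        seed=seed,
        genome=GenomeSpec((("chr1", 3_000_000), ("chr2", 3_000_000))),
        n_enhancers=n_enh,
        n_genes=0,
        n_de_genes=0,
    )


OPPOSITE_CLASS = {
    "both_up": "both_down",
    "both_down": "both_up",
    "acet_up_only": "acet_down_only",
    "acet_down_only": "acet_up_only",
    "atac_up_only": "atac_down_only",
    "atac_down_only": "atac_up_only",
}


def motif_recovery(seed: int, workdir=None) -> dict:
    """End-to-end run through classification and motif enrichment.

    For every planted (class, motif) pair, reports whether the motif was
    called enriched (p < 1e-10) in its own class and its p-value in the
    opposite-direction class (expected non-enriched).
    """
    cfg = motif_recovery_config(seed)
    pcfg = PipelineConfig(seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir else Path(tmp)
        dataset = base / "dataset"
        work = base / "work"
        write_dataset(cfg, dataset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pipeline.stage_bin(dataset, work, pcfg)
            pipeline.stage_normalize(dataset, work, pcfg)
            pipeline.stage_diffacet(dataset, work, pcfg)
            pipeline.stage_integrate(dataset, work, pcfg)
            table = pipeline.stage_motifs(dataset, work, pcfg)
    truth = build_truth(cfg)
    planted: dict[str, set[str]] = {}
    for r in truth.enhancers.itertuples():
        if r.motifs:
            planted.setdefault(r.region_class, set()).update(r.motifs.split(","))
    results = {}
    for cls, motif_ids in sorted(planted.items()):
        for mid in sorted(motif_ids):
            own = table[(table["region_class"] == cls) & (table["motif_id"] == mid)]
            opp_cls = OPPOSITE_CLASS[cls]
            opp = table[
                (table["region_class"] == opp_cls) & (table["motif_id"] == mid)
            ]
            results[f"{cls}:{mid}"] = {
                "enriched_own": bool(len(own) and own["enriched"].iloc[0]),
                "p_own": float(own["p"].iloc[0]) if len(own) else float("nan"),
                "p_opposite": float(opp["p"].iloc[0]) if len(opp) else float("nan"),
            }
    n = len(results)
    ok = sum(
        r["enriched_own"]
        and (np.isnan(r["p_opposite"]) or r["p_opposite"] > 0.01)
        for r in results.values()
    )
    return {"pairs": results, "recovery_rate": ok / n if n else float("nan")}
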