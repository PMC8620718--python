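"""End-to-end pipeline: simulate, quantify, test, integrate, report.

Stages communicate through tab-delimited files in a working directory so any
stage can be re-run in isolation from the command line; ``run_all`` chains
them. All floats are written with a fixed format and all random choices are
seeded, so two runs with the same configuration produce byte-identical
output tables.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atac_integration, binning_signal, differential, expression_concordance
from . import motif_enrichment as me
from .genome_io import (
    GenomeSpec,
    GenomicInterval,
    make_bin_grid,
    read_bed,
    read_chrom_sizes,
    read_fasta,
    read_gene_table,
    read_pwm_jaspar,
)
from .synthetic_data import SimConfig, SimTruth, write_dataset

log = logging.getLogger("acetdiff")

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Every analysis threshold in one place (defaults are the study's)."""

    bin_width: int = 500
    background_threshold: int = 20
    promoter_flank: int = 2000
    q_threshold: float = 0.05
    atac_pad: int = 500
    summit_width: int = 200
    enrichment_alpha: float = 1e-10
    score_fraction: float = 0.8
    background_ratio: int = 2
    gc_tol: float = 0.02
    prior_df: int = differential.DEFAULT_PRIOR_DF
    seed: int = 0

    def __post_init__(self):
        if min(self.bin_width, self.promoter_flank, self.summit_width) <= 0:
            raise ValueError("window sizes must be positive")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if not 0 < self.score_fraction <= 1:
            raise ValueError("score_fraction must be in (0, 1]")
        if self.atac_pad < 0 or self.background_threshold < 0:
            raise ValueError("pads and thresholds must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _read_manifest(dataset_dir: Path) -> dict:
    with open(dataset_dir / "config.yaml") as fh:
        return yaml.safe_load(fh)


def _load_fragments(dataset_dir: Path, manifest: dict) -> dict[str, pd.DataFrame]:
    out = {}
    for sample, info in manifest["samples"].items():
        path = dataset_dir / info["fragments"]
        if not path.exists():
            raise FileNotFoundError(f"missing fragment file {path}")
        out[sample] = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end"],
            usecols=[0, 1, 2],
        )
    return out


def _write_table(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages

def run_simulate(config: SimConfig, outdir, force: bool = False) -> SimTruth:
    """Write a complete synthetic dataset; refuses a non-empty dir without force."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force to overwrite)")
    log.info("simulate: seed=%d genome=%s bp", config.seed, config.genome.total_length)
    truth = write_dataset(config, outdir)
    log.info(
        "simulate: %d enhancers, %d genes, %d+%d fragment samples",
        len(truth.enhancers), len(truth.genes), config.n_control, config.n_case,
    )
    return truth


def stage_bin(dataset_dir, workdir, cfg: PipelineConfig) -> pd.DataFrame:
    """Count fragments per bin for every sample -> bin_counts_raw.tsv."""
    dataset_dir, workdir = Path(dataset_dir), Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = _read_manifest(dataset_dir)
    genome = read_chrom_sizes(dataset_dir / "chrom.sizes")
    grid = make_bin_grid(genome, cfg.bin_width)
    fragments = _load_fragments(dataset_dir, manifest)
    conditions = {s: info["condition"] for s, info in manifest["samples"].items()}
    cm = binning_signal.bin_count_matrix(fragments, grid, conditions)
    table = pd.concat([cm.features.reset_index(drop=True), cm.values], axis=1)
    _write_table(table, workdir / "bin_counts_raw.tsv")
    log.info("bin: %d bins x %d samples", len(table), len(cm.samples))
    return table


def _split_counts(table: pd.DataFrame):
    feature_cols = ["chrom", "start", "end"]
    samples = [c for c in table.columns if c not in feature_cols]
    return table[feature_cols], table[samples]


def stage_normalize(dataset_dir, workdir, cfg: PipelineConfig) -> pd.DataFrame:
    """Background-subtract + quantile-normalize -> bin_counts_norm.tsv."""
    workdir = Path(workdir)
    manifest = _read_manifest(Path(dataset_dir))
    conditions = {s: info["condition"] for s, info in manifest["samples"].items()}
    table = pd.read_csv(workdir / "bin_counts_raw.tsv", sep="\t")
    features, values = _split_counts(table)
    cm = binning_signal.CountMatrix(features, values, conditions)
    normed, report = binning_signal.normalize_counts(cm, cfg.background_threshold)
    out = pd.concat([features.reset_index(drop=True), normed.values], axis=1)
    _write_table(out, workdir / "bin_counts_norm.tsv")
    _write_table(report, workdir / "background.tsv")
    log.info(
        "normalize: backgrounds %s",
        ", ".join(f"{r.sample}={r.background:.2f}" for r in report.itertuples()),
    )
    return out


def stage_diffacet(dataset_dir, workdir, cfg: PipelineConfig) -> pd.DataFrame:
    """Moderated NB test per bin, BH, merge -> bin_diff.tsv + regions.bed."""
    workdir = Path(workdir)
    manifest = _read_manifest(Path(dataset_dir))
    conditions = {s: info["condition"] for s, info in manifest["samples"].items()}
    table = pd.read_csv(workdir / "bin_counts_norm.tsv", sep="\t")
    features, values = _split_counts(table)
    features, values = differential.drop_all_zero(features, values)
    # quantile normalization equalizes library distributions; size factors 1
    res = differential.nb_wald_test(values, conditions, prior_df=cfg.prior_df)
    res = differential.finalize_results(res, cfg.q_threshold)
    bin_diff = pd.concat([features.reset_index(drop=True),
                          res.reset_index(drop=True)], axis=1)
    _write_table(bin_diff, workdir / "bin_diff.tsv")
    regions = differential.merge_significant_bins(bin_diff, cfg.q_threshold)
    _write_table(regions, workdir / "regions.tsv")
    bed = regions[["chrom", "start", "end", "direction", "score"]].copy()
    bed["strand"] = "."
    bed.to_csv(
        workdir / "regions.bed", sep="\t", header=False, index=False,
        float_format="%.1f",
    )
    n_up = int((regions["direction"] == "up").sum())
    n_down = int((regions["direction"] == "down").sum())
    log.info("diffacet: %d bins tested, %d regions (%d up / %d down)",
             len(bin_diff), len(regions), n_up, n_down)
    return regions


def stage_promoters(dataset_dir, workdir, cfg: PipelineConfig) -> pd.DataFrame:
    """Promoter-window differential acetylation -> promoter_diff.tsv."""
    dataset_dir, workdir = Path(dataset_dir), Path(workdir)
    manifest = _read_manifest(dataset_dir)
    genome = read_chrom_sizes(dataset_dir / "chrom.sizes")
    genes = read_gene_table(dataset_dir / "genes.tsv", genome)
    fragments = _load_fragments(dataset_dir, manifest)
    conditions = {s: info["condition"] for s, info in manifest["samples"].items()}
    res = differential.promoter_differential(
        fragments, genes, genome, conditions,
        flank=cfg.promoter_flank,
        background_threshold=cfg.background_threshold,
        q_threshold=cfg.q_threshold,
        prior_df=cfg.prior_df,
    )
    _write_table(res.rename_axis("gene_id"), workdir / "promoter_diff.tsv", index=True)
    log.info("promoters: %d genes, %d tested, %d significant",
             len(res), int(res["tested"].sum()), int(res["significant"].sum()))
    return res


def stage_diffexpr(dataset_dir, workdir, cfg: PipelineConfig) -> pd.DataFrame:
    """Differential expression on the RNA count table -> expression_de.tsv."""
    dataset_dir, workdir = Path(dataset_dir), Path(workdir)
    manifest = _read_manifest(dataset_dir)
    counts = pd.read_csv(dataset_dir / "expression_counts.tsv", sep="\t",
                         index_col="gene_id")
    res = expression_concordance.de_genes(
        counts, manifest["rna_samples"], cfg.q_threshold, cfg.prior_df
    )
    _write_table(res.rename_axis("gene_id"), workdir / "expression_de.tsv", index=True)
    log.info("diffexpr: %d genes tested, %d significant",
             len(res), int(res["significant"].sum()))
    return res


def stage_concordance(dataset_dir, workdir, cfg: PipelineConfig) -> dict:
    """Join DE and promoter tables -> concordance.tsv + summary."""
    workdir = Path(workdir)
    de = pd.read_csv(workdir / "expression_de.tsv", sep="\t", index_col="gene_id")
    prom = pd.read_csv(workdir / "promoter_diff.tsv", sep="\t", index_col="gene_id")
    records, summary = expression_concordance.concordance(de, prom, cfg.q_threshold)
    _write_table(records, workdir / "concordance.tsv")
    with open(workdir / "concordance_summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    log.info("concordance: %s", summary)
    return summary


def stage_integrate(dataset_dir, workdir, cfg: PipelineConfig) -> pd.DataFrame:
    """Classify called regions against directional ATAC peaks -> venn.tsv."""
    dataset_dir, workdir = Path(dataset_dir), Path(workdir)
    genome = read_chrom_sizes(dataset_dir / "chrom.sizes")
    regions = pd.read_csv(workdir / "regions.tsv", sep="\t")
    atac = {
        "up": read_bed(dataset_dir / "atac_gained.bed", genome),
        "down": read_bed(dataset_dir / "atac_lost.bed", genome),
    }
    acet_rows, atac_rows, venn_rows = [], [], []
    for direction in ("down", "up"):
        sel = regions[regions["direction"] == direction]
        acet = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=direction)
            for r in sel.itertuples()
        ]
        peaks = [
            GenomicInterval(p.chrom, p.start, p.end, name=direction)
            for p in atac[direction]
        ]
        acet_cls, atac_cls, venn = atac_integration.classify_regions(
            acet, peaks, direction, genome, cfg.atac_pad
        )
        for iv, c in zip(acet, acet_cls):
            acet_rows.append(dict(chrom=iv.chrom, start=iv.start, end=iv.end,
                                  region_class=c))
        for iv, c in zip(peaks, atac_cls):
            atac_rows.append(dict(chrom=iv.chrom, start=iv.start, end=iv.end,
                                  region_class=c))
        venn_rows.append(dict(direction=direction, acet_only=venn.acet_only,
                              both_acet=venn.both_acet, both_atac=venn.both_atac,
                              atac_only=venn.atac_only))
    pd.DataFrame(acet_rows).to_csv(workdir / "classified_acet.bed", sep="\t",
                                   header=False, index=False)
    pd.DataFrame(atac_rows).to_csv(workdir / "classified_atac.bed", sep="\t",
                                   header=False, index=False)
    venn = pd.DataFrame(venn_rows)
    _write_table(venn, workdir / "venn.tsv")
    log.info("integrate: %s", venn.to_dict("records"))
    return venn


def _class_windows(workdir: Path, genome: GenomeSpec, cfg: PipelineConfig):
    """Scan windows per class: ATAC summits where ATAC is involved, else
    acetylation-region centres."""
    acet = pd.read_csv(
        workdir / "classified_acet.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "region_class"],
    )
    atac = pd.read_csv(
        workdir / "classified_atac.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "region_class"],
    )
    windows: dict[str, list[GenomicInterval]] = {
        c: [] for c in atac_integration.REGION_CLASSES
    }
    for df, source in ((acet, "acet"), (atac, "atac")):
        for r in df.itertuples():
            cls = r.region_class
            if cls.startswith("both") and source == "acet":
                continue  # both classes anchor on the ATAC summit
            iv = GenomicInterval(r.chrom, int(r.start), int(r.end), name=cls)
            windows[cls].append(iv)
    return {
        cls: atac_integration.summit_windows(ivs, genome, cfg.summit_width)
        for cls, ivs in windows.items()
        if ivs
    }


def _background_pool(
    genome: GenomeSpec,
    exclude: list[GenomicInterval],
    cfg: PipelineConfig,
    n_max: int = 4000,
    stride: int = 2000,
) -> list[GenomicInterval]:
    """Candidate background windows on a genome lattice, away from targets."""
    half = cfg.summit_width // 2
    candidates = []
    for chrom, length in genome.chroms:
        for c in range(stride, length - stride, stride):
            candidates.append(GenomicInterval(chrom, c - half, c + half))
    flags = atac_integration._overlap_flags(candidates, exclude) if exclude else (
        np.zeros(len(candidates), dtype=bool)
    )
    pool = [w for w, hit in zip(candidates, flags) if not hit]
    if len(pool) > n_max:
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(len(pool), size=n_max, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    return pool


def stage_motifs(dataset_dir, workdir, cfg: PipelineConfig) -> pd.DataFrame:
    """Per-class known-motif enrichment -> motif_enrichment.tsv."""
    dataset_dir, workdir = Path(dataset_dir), Path(workdir)
    genome = read_chrom_sizes(dataset_dir / "chrom.sizes")
    sequences = read_fasta(dataset_dir / "genome.fa")
    motifs = read_pwm_jaspar(dataset_dir / "motifs.jaspar")
    windows = _class_windows(workdir, genome, cfg)
    all_targets = [w for ws in windows.values() for w in ws]
    pool = _background_pool(genome, all_targets, cfg)
    table = me.per_class_enrichment(
        windows, pool, motifs, sequences,
        score_fraction=cfg.score_fraction,
        ratio=cfg.background_ratio,
        gc_tol=cfg.gc_tol,
        seed=cfg.seed,
        alpha=cfg.enrichment_alpha,
    )
    _write_table(table, workdir / "motif_enrichment.tsv")
    log.info("motifs: %d class/motif tests, %d enriched",
             len(table), int(table["enriched"].sum()) if len(table) else 0)
    return table


def run_all(dataset_dir, workdir, cfg: PipelineConfig | None = None) -> dict:
    """Run every stage in order and write a combined summary."""
    cfg = cfg or PipelineConfig()
    dataset_dir, workdir = Path(dataset_dir), Path(workdir)
    for required in ("config.yaml", "chrom.sizes", "genes.tsv",
                     "expression_counts.tsv", "atac_gained.bed", "atac_lost.bed",
                     "genome.fa", "motifs.jaspar"):
        if not (dataset_dir / required).exists():
            raise FileNotFoundError(f"missing input {dataset_dir / required}")
    workdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(workdir / "pipeline_config.yaml")
    stage_bin(dataset_dir, workdir, cfg)
    stage_normalize(dataset_dir, workdir, cfg)
    regions = stage_diffacet(dataset_dir, workdir, cfg)
    stage_promoters(dataset_dir, workdir, cfg)
    stage_diffexpr(dataset_dir, workdir, cfg)
    conc = stage_concordance(dataset_dir, workdir, cfg)
    venn = stage_integrate(dataset_dir, workdir, cfg)
    motifs = stage_motifs(dataset_dir, workdir, cfg)
    summary = {
        "n_regions_up": int((regions["direction"] == "up").sum()),
        "n_regions_down": int((regions["direction"] == "down").sum()),
        "venn": venn.to_dict("records"),
        "concordance": conc,
        "n_enriched_motif_tests": int(motifs["enriched"].sum()) if len(motifs) else 0,
    }
    with open(workdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# evaluation against simulated truth

def _covered_fraction(iv: tuple, regions: pd.DataFrame) -> float:
    chrom, start, end, direction = iv
    sel = regions[(regions["chrom"] == chrom) & (regions["direction"] == direction)]
    cov = 0
    for r in sel.itertuples():
        cov += max(0, min(end, r.end) - max(start, r.start))
    return cov / (end - start)


def region_recovery_metrics(
    regions: pd.DataFrame, planted: list[tuple]
) -> dict:
    """Sensitivity (>= 50% base coverage, same direction) and observed FDR.

    ``planted`` holds (chrom, start, end, direction) tuples of truly
    differential intervals; a called region overlapping none of them in its
    direction is a false positive.
    """
    if planted:
        recovered = sum(_covered_fraction(iv, regions) >= 0.5 for iv in planted)
        sensitivity = recovered / len(planted)
    else:
        sensitivity = float("nan")
    if len(regions):
        fp = sum(
            not any(
                c == r.chrom and d == r.direction and s < r.end and r.start < e
                for c, s, e, d in planted
            )
            for r in regions.itertuples()
        )
        fdr = fp / len(regions)
    else:
        fdr = float("nan")
    return {
        "n_planted": len(planted),
        "n_called_regions": int(len(regions)),
        "region_sensitivity": float(sensitivity),
        "region_fdr": float(fdr),
    }


def evaluate_against_truth(workdir, dataset_dir, cfg: PipelineConfig | None = None) -> dict:
    """Recovery metrics of the pipeline's calls against the simulator's truth.

    A planted differential interval counts as recovered when >= 50% of its
    bases are covered by same-direction called regions; a called region is a
    false positive when it overlaps no same-direction planted interval.
    """
    cfg = cfg or PipelineConfig()
    workdir, dataset_dir = Path(workdir), Path(dataset_dir)
    truth = SimTruth.read(
        dataset_dir / "truth_enhancers.tsv", dataset_dir / "truth_genes.tsv"
    )
    genome = read_chrom_sizes(dataset_dir / "chrom.sizes")
    regions = pd.read_csv(workdir / "regions.tsv", sep="\t")
    for chrom in regions["chrom"].unique():
        if chrom not in genome:
            raise ValueError(f"results chromosome {chrom} not in truth genome")

    planted = []
    for r in truth.enhancers.itertuples():
        if r.fold != 1.0:
            planted.append(
                (r.chrom, r.start, r.end, "up" if r.fold > 1 else "down")
            )
    flank = cfg.promoter_flank
    for g in truth.genes.itertuples():
        if g.promoter_fold != 1.0:
            planted.append(
                (
                    g.chrom,
                    max(0, g.tss - flank),
                    min(genome.lengths[g.chrom], g.tss + flank),
                    "up" if g.promoter_fold > 1 else "down",
                )
            )

    metrics = region_recovery_metrics(regions, planted)

    conc_path = workdir / "concordance_summary.yaml"
    if conc_path.exists():
        with open(conc_path) as fh:
            conc = yaml.safe_load(fh)
        metrics["concordance_fraction"] = conc.get("concordance_fraction")

    motif_path = workdir / "motif_enrichment.tsv"
    if motif_path.exists():
        table = pd.read_csv(motif_path, sep="\t")
        planted_map: dict[str, set[str]] = {}
        for r in truth.enhancers.itertuples():
            if r.motifs:
                planted_map.setdefault(r.region_class, set()).update(
                    r.motifs.split(",")
                )
        flags = {}
        for cls, motif_ids in sorted(planted_map.items()):
            sub = table[table["region_class"] == cls]
            for mid in sorted(motif_ids):
                row = sub[sub["motif_id"] == mid]
                flags[f"{cls}:{mid}"] = bool(
                    len(row) and row["enriched"].iloc[0]
                )
        metrics["motif_recovery"] = flags
        metrics["motif_recovery_rate"] = (
            sum(flags.values()) / len(flags) if flags else float("nan")
        )
    return metrics
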