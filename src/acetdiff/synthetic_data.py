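"""Two-condition CUT&RUN / ATAC / expression simulator with known ground truth.

The generator emulates the statistical structure of an infarct border-zone vs
healthy-ventricle cardiomyocyte experiment: negative-binomially distributed
fragment counts per 500 bp bin composed of a uniform background plus
enhancer-shaped peaks, condition-dependent fold changes at labelled regions,
directional ATAC peaks at a subset of those regions, motif instances planted
in class-specific enhancers, and nuclear RNA counts whose fold-change sign is
coupled to promoter acetylation changes for a configurable fraction of
differential genes.

A deliberate feature is the large set of *stable* (class ``null``) peaks with
log-normal amplitudes. Quantile normalization maps sample ranks onto a common
reference, so differential signal survives it only relative to a backdrop of
non-differential signal — exactly as in real H3K27ac data, where differential
regions are a minority among tens of thousands of stable peaks. Without the
backdrop the normalization would erase every planted effect.

Every output is a pure function of :class:`SimConfig`; each operation draws
from an independent seeded stream so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    GenomeSpec,
    GenomicInterval,
    GeneModel,
    PWM,
    make_bin_grid,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_gene_table,
)

REGION_CLASSES = (
    "acet_down_only",
    "both_down",
    "atac_down_only",
    "acet_up_only",
    "both_up",
    "atac_up_only",
)
NULL_CLASS = "null"

ACET_UP_CLASSES = ("acet_up_only", "both_up")
ACET_DOWN_CLASSES = ("acet_down_only", "both_down")
ATAC_UP_CLASSES = ("both_up", "atac_up_only")
ATAC_DOWN_CLASSES = ("both_down", "atac_down_only")

_DEFAULT_GENOME = GenomeSpec(
    (("chr1", 1_000_000), ("chr2", 1_000_000), ("chr3", 1_000_000))
)

# Class -> planted motif ids (resolved against the motif library).
DEFAULT_MOTIF_MAP: dict[str, tuple[str, ...]] = {
    "both_up": ("AP1",),
    "both_down": ("MEF2", "PPAR_RXR"),
    "acet_down_only": ("MEF2", "PPAR_RXR"),
    "atac_up_only": ("KLF",),
    "acet_up_only": (),
    "atac_down_only": (),
}


def _default_counts() -> dict[str, int]:
    d = {c: 40 for c in REGION_CLASSES}
    d[NULL_CLASS] = 200
    return d


def _default_folds() -> dict[str, float]:
    return {
        "acet_up_only": 4.0,
        "both_up": 4.0,
        "acet_down_only": 0.25,
        "both_down": 0.25,
        "atac_up_only": 1.0,
        "atac_down_only": 1.0,
        NULL_CLASS: 1.0,
    }


def _default_elevations() -> dict[str, float]:
    # Control-side peak elevation (counts/bin over background). Lost classes
    # start high so the low side of the change still sits at ~50 counts/bin.
    return {
        "acet_up_only": 50.0,
        "both_up": 50.0,
        "acet_down_only": 200.0,
        "both_down": 200.0,
        "atac_up_only": 50.0,
        "atac_down_only": 50.0,
    }


@dataclass
class SimConfig:
    """Study-condition parameters for the simulator.

    Defaults mirror the source experiment: 3 vs 3 CUT&RUN replicates, 3 vs 5
    nuclear RNA replicates, 500 bp bins, GC 0.42, and ~65% of differential
    genes with sign-coupled promoter acetylation changes.
    """

    seed: int = 0
    genome: GenomeSpec = field(default_factory=lambda: _DEFAULT_GENOME)
    bin_width: int = 500
    n_control: int = 3
    n_case: int = 3
    n_enhancers: dict[str, int] = field(default_factory=_default_counts)
    enhancer_width: int = 600
    fold_change: dict[str, float] = field(default_factory=_default_folds)
    enhancer_elevation: dict[str, float] = field(default_factory=_default_elevations)
    null_elevation_median: float = 50.0
    null_elevation_sigma: float = 1.0
    background_rate: float = 10.0
    dispersion: float = 0.05
    library_size_factors: tuple[float, ...] | None = None
    fragment_length: int = 150
    gc_content: float = 0.42
    # expression arm
    n_control_rna: int = 3
    n_case_rna: int = 5
    n_genes: int = 150
    n_de_genes: int = 60
    coupled_fraction: float = 0.65
    expression_lfc: float = 2.0
    expression_base_mean: float = 200.0
    expression_sigma: float = 1.0
    expression_dispersion: float = 0.05
    promoter_flank: int = 2000
    promoter_elevation: float = 50.0
    motif_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_MAP)
    )

    def __post_init__(self):
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("need at least one sample per condition")
        if any(n < 0 for n in self.n_enhancers.values()):
            raise ValueError("enhancer counts must be >= 0")
        if any(f <= 0 for f in self.fold_change.values()):
            raise ValueError("fold changes must be > 0")
        if self.dispersion < 0 or self.expression_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.coupled_fraction <= 1:
            raise ValueError("coupled_fraction must be in [0, 1]")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        n = self.n_control + self.n_case
        if self.library_size_factors is not None:
            if len(self.library_size_factors) != n:
                raise ValueError("need one library size factor per sample")
            if any(s <= 0 for s in self.library_size_factors):
                raise ValueError("library size factors must be > 0")

    @property
    def sample_names(self) -> list[str]:
        return [f"control_{i+1}" for i in range(self.n_control)] + [
            f"case_{i+1}" for i in range(self.n_case)
        ]

    @property
    def conditions(self) -> dict[str, str]:
        return {
            s: ("control" if s.startswith("control") else "case")
            for s in self.sample_names
        }

    @property
    def rna_sample_names(self) -> list[str]:
        return [f"rna_control_{i+1}" for i in range(self.n_control_rna)] + [
            f"rna_case_{i+1}" for i in range(self.n_case_rna)
        ]

    @property
    def rna_conditions(self) -> dict[str, str]:
        return {
            s: ("control" if "control" in s else "case") for s in self.rna_sample_names
        }


@dataclass
class SimTruth:
    """Planted ground truth: labelled enhancers and gene-level effects."""

    enhancers: pd.DataFrame  # chrom,start,end,region_class,elevation,fold,true_log2fc,atac_direction,motifs
    genes: pd.DataFrame  # gene_id,chrom,strand,tss,expression_log2fc,promoter_log2fc,promoter_elevation,promoter_fold

    def write(self, enhancer_path, gene_path) -> None:
        self.enhancers.to_csv(enhancer_path, sep="\t", index=False)
        self.genes.to_csv(gene_path, sep="\t", index=False)

    @classmethod
    def read(cls, enhancer_path, gene_path) -> "SimTruth":
        enh = pd.read_csv(enhancer_path, sep="\t", keep_default_na=False)
        genes = pd.read_csv(gene_path, sep="\t", keep_default_na=False)
        return cls(enh, genes)


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def _atac_direction(region_class: str) -> str:
    if region_class in ATAC_UP_CLASSES:
        return "up"
    if region_class in ATAC_DOWN_CLASSES:
        return "down"
    return "none"


def build_truth(config: SimConfig) -> SimTruth:
    """Lay out enhancers, stable peaks and genes without overlap, label them.

    Items are shuffled and then placed left-to-right across chromosomes with
    random gaps, so class membership carries no positional signal.
    """
    rng = _rng(config, 1)

    items: list[tuple[str, str, int]] = []  # (kind, label, span_bp)
    for cls in list(REGION_CLASSES) + [NULL_CLASS]:
        for _ in range(config.n_enhancers.get(cls, 0)):
            items.append(("enhancer", cls, config.enhancer_width))
    for i in range(config.n_genes):
        items.append(("gene", f"g{i+1:04d}", 2 * config.promoter_flank))
    order = rng.permutation(len(items))

    margin = config.bin_width
    chrom_iter = iter(config.genome.chroms)
    chrom, chrom_len = next(chrom_iter)
    pos = margin
    placed: list[tuple[str, str, str, int, int]] = []  # kind,label,chrom,start,end
    for idx in order:
        kind, label, span = items[idx]
        gap = int(rng.integers(config.bin_width, 3 * config.bin_width))
        while True:
            start = pos + gap
            if start + span + margin <= chrom_len:
                break
            try:
                chrom, chrom_len = next(chrom_iter)
            except StopIteration:
                raise ValueError(
                    "genome too small for the configured enhancers and genes"
                ) from None
            pos = margin
        placed.append((kind, label, chrom, start, start + span))
        pos = start + span

    enh_rows = []
    gene_rows = []
    de_flags = _assign_expression_effects(config, rng)
    gene_counter = 0
    for kind, label, chrom, start, end in placed:
        if kind == "enhancer":
            cls = label
            fold = config.fold_change.get(cls, 1.0)
            if cls == NULL_CLASS:
                elev = float(
                    np.exp(
                        rng.normal(
                            math.log(config.null_elevation_median),
                            config.null_elevation_sigma,
                        )
                    )
                )
            else:
                elev = config.enhancer_elevation.get(cls, 50.0)
            motifs = ",".join(config.motif_map.get(cls, ()))
            enh_rows.append(
                dict(
                    chrom=chrom,
                    start=start,
                    end=end,
                    region_class=cls,
                    elevation=elev,
                    fold=fold,
                    true_log2fc=math.log2(fold),
                    atac_direction=_atac_direction(cls),
                    motifs=motifs,
                )
            )
        else:
            expr_lfc, coupled = de_flags[gene_counter]
            gene_counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start + config.promoter_flank
            if coupled and expr_lfc != 0:
                prom_fold = 4.0 if expr_lfc > 0 else 0.25
                prom_elev = (
                    config.promoter_elevation
                    if expr_lfc > 0
                    else config.promoter_elevation / prom_fold
                )
                prom_lfc = math.log2(prom_fold)
            else:
                prom_fold, prom_lfc = 1.0, 0.0
                prom_elev = config.promoter_elevation
            gene_rows.append(
                dict(
                    gene_id=label,
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    expression_log2fc=expr_lfc,
                    promoter_log2fc=prom_lfc,
                    promoter_elevation=prom_elev,
                    promoter_fold=prom_fold,
                )
            )

    enh = pd.DataFrame(
        enh_rows,
        columns=[
            "chrom", "start", "end", "region_class", "elevation", "fold",
            "true_log2fc", "atac_direction", "motifs",
        ],
    )
    genes = pd.DataFrame(
        gene_rows,
        columns=[
            "gene_id", "chrom", "strand", "tss", "expression_log2fc",
            "promoter_log2fc", "promoter_elevation", "promoter_fold",
        ],
    ).sort_values("gene_id", kind="mergesort", ignore_index=True)
    enh = enh.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)
    return SimTruth(enh, genes)


def _assign_expression_effects(
    config: SimConfig, rng: np.random.Generator
) -> list[tuple[float, bool]]:
    """Per gene: (true expression log2FC, promoter-coupled flag)."""
    n = config.n_genes
    n_de = min(config.n_de_genes, n)
    flags = [(0.0, False)] * n
    de_idx = rng.choice(n, size=n_de, replace=False)
    n_coupled = int(round(config.coupled_fraction * n_de))
    coupled = set(de_idx[:n_coupled].tolist())
    out = list(flags)
    for j, gi in enumerate(de_idx):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[gi] = (sign * config.expression_lfc, gi in coupled)
    return out


# ---------------------------------------------------------------------------
# sequence

def simulate_genome_sequence(config: SimConfig) -> dict[str, str]:
    """I.i.d. nucleotides at the configured GC content, per chromosome."""
    rng = _rng(config, 2)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for name, length in config.genome.chroms:
        idx = rng.choice(4, size=length, p=p)
        out[name] = alphabet[idx].tobytes().decode("ascii")
    return out


def plant_motifs(
    sequences: dict[str, str],
    truth: SimTruth,
    pwm_library: list[PWM],
    config: SimConfig,
) -> dict[str, str]:
    """Embed one sampled instance of each class motif at every enhancer centre.

    Multi-motif classes place their instances side by side, centred jointly.
    """
    rng = _rng(config, 3)
    by_id = {p.motif_id: p for p in pwm_library}
    bufs = {name: bytearray(seq, "ascii") for name, seq in sequences.items()}
    alphabet = b"ACGT"
    for row in truth.enhancers.itertuples():
        if not row.motifs:
            continue
        motif_ids = row.motifs.split(",")
        pwms = []
        for mid in motif_ids:
            if mid not in by_id:
                raise KeyError(f"motif {mid} not in library")
            pwms.append(by_id[mid])
        total = sum(len(p) for p in pwms)
        width = row.end - row.start
        if total > width:
            raise ValueError(
                f"motifs ({total} bp) longer than enhancer ({width} bp)"
            )
        center = (row.start + row.end) // 2
        offset = center - total // 2
        buf = bufs[row.chrom]
        for pwm in pwms:
            for i in range(len(pwm)):
                letter = alphabet[rng.choice(4, p=pwm.matrix[i])]
                buf[offset + i] = letter
            offset += len(pwm)
    return {name: bytes(b).decode("ascii") for name, b in bufs.items()}


# ---------------------------------------------------------------------------
# fragments

def _bin_means(config: SimConfig, truth: SimTruth):
    """Per-bin control/case expected counts (before library size factors)."""
    grid = make_bin_grid(config.genome, config.bin_width)
    elev = np.zeros(grid.n_bins)
    fold = np.ones(grid.n_bins)
    for row in truth.enhancers.itertuples():
        b0 = int(grid.bin_index(row.chrom, row.start))
        b1 = int(grid.bin_index(row.chrom, row.end - 1))
        elev[b0 : b1 + 1] = row.elevation
        fold[b0 : b1 + 1] = row.fold
    for row in truth.genes.itertuples():
        w0 = max(0, row.tss - config.promoter_flank)
        w1 = min(config.genome.lengths[row.chrom], row.tss + config.promoter_flank)
        b0 = int(grid.bin_index(row.chrom, w0))
        b1 = int(grid.bin_index(row.chrom, w1 - 1))
        elev[b0 : b1 + 1] = row.promoter_elevation
        fold[b0 : b1 + 1] = row.promoter_fold
    mu_control = config.background_rate + elev
    mu_case = config.background_rate + elev * fold
    return grid, mu_control, mu_case


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean mu, variance mu + alpha*mu^2) via the gamma-Poisson mixture."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / alpha, mu * alpha)
    return rng.poisson(lam)


def simulate_fragments(
    config: SimConfig, truth: SimTruth
) -> dict[str, pd.DataFrame]:
    """Per-sample fragment tables (chrom, start, end), midpoints inside bins."""
    grid, mu_control, mu_case = _bin_means(config, truth)
    sizes = (
        np.asarray(config.library_size_factors, float)
        if config.library_size_factors is not None
        else np.ones(config.n_control + config.n_case)
    )
    names = np.array(config.genome.names)
    flen = config.fragment_length
    out = {}
    for j, sample in enumerate(config.sample_names):
        rng = _rng(config, 100 + j)
        mu = mu_control if config.conditions[sample] == "control" else mu_case
        counts = _nb_draw(rng, sizes[j] * mu, config.dispersion)
        bins = np.repeat(np.arange(grid.n_bins), counts)
        bstart = grid.starts[bins]
        bend = grid.ends[bins]
        span = np.maximum(bend - flen - bstart, 1)
        starts = bstart + rng.integers(0, span)
        chrom_len = np.array([config.genome.lengths[n] for n in names])
        ends = np.minimum(starts + flen, chrom_len[grid.chrom_idx[bins]])
        out[sample] = pd.DataFrame(
            {
                "chrom": names[grid.chrom_idx[bins]],
                "start": starts.astype(np.int64),
                "end": ends.astype(np.int64),
            }
        )
    return out


# ---------------------------------------------------------------------------
# ATAC peaks and expression

def simulate_atac_peaks(truth: SimTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directional ATAC peaks: one per enhancer whose class has an ATAC arm.

    The peak equals the enhancer interval; its 200 bp summit is the centre
    +/- 100 bp.
    """
    frames = {}
    for direction in ("up", "down"):
        sel = truth.enhancers[truth.enhancers["atac_direction"] == direction]
        center = (sel["start"] + sel["end"]) // 2
        frames[direction] = pd.DataFrame(
            {
                "chrom": sel["chrom"],
                "start": sel["start"],
                "end": sel["end"],
                "name": sel["region_class"],
                "summit_start": center - 100,
                "summit_end": center + 100,
            }
        ).reset_index(drop=True)
    return frames["up"], frames["down"]


def simulate_expression(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Gene x sample NB count table with log-normal baselines.

    Coupled differential genes change with the sign of their planted promoter
    acetylation effect; all other genes are null.
    """
    rng = _rng(config, 4)
    genes = truth.genes
    base = np.exp(
        rng.normal(
            math.log(config.expression_base_mean),
            config.expression_sigma,
            len(genes),
        )
    )
    lfc = genes["expression_log2fc"].to_numpy(float)
    cols = {}
    for sample in config.rna_sample_names:
        mu = base * np.where(
            config.rna_conditions[sample] == "case", 2.0**lfc, 1.0
        )
        cols[sample] = _nb_draw(rng, mu, config.expression_dispersion)
    return pd.DataFrame(cols, index=genes["gene_id"]).rename_axis("gene_id")


# ---------------------------------------------------------------------------
# dataset writer

def write_dataset(config: SimConfig, outdir, pwm_library: list[PWM] | None = None):
    """Generate every synthetic input file plus the ground truth under ``outdir``."""
    from pathlib import Path

    import yaml

    from .motif_enrichment import default_motif_library

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if pwm_library is None:
        pwm_library = default_motif_library()

    truth = build_truth(config)
    sequences = plant_motifs(
        simulate_genome_sequence(config), truth, pwm_library, config
    )
    fragments = simulate_fragments(config, truth)
    atac_up, atac_down = simulate_atac_peaks(truth)
    expression = simulate_expression(config, truth)

    write_chrom_sizes(config.genome, outdir / "chrom.sizes")
    write_fasta(sequences, outdir / "genome.fa")
    from .genome_io import write_pwm_jaspar

    write_pwm_jaspar(pwm_library, outdir / "motifs.jaspar")
    for sample, frags in fragments.items():
        frags.to_csv(
            outdir / f"fragments_{sample}.bed", sep="\t", header=False, index=False
        )
    for direction, table in (("gained", atac_up), ("lost", atac_down)):
        table[["chrom", "start", "end", "name"]].to_csv(
            outdir / f"atac_{direction}.bed", sep="\t", header=False, index=False
        )
    genes = [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.tss))
        for r in truth.genes.itertuples()
    ]
    write_gene_table(genes, outdir / "genes.tsv")
    expression.to_csv(outdir / "expression_counts.tsv", sep="\t")
    truth.write(outdir / "truth_enhancers.tsv", outdir / "truth_genes.tsv")

    manifest = {
        "seed": config.seed,
        "bin_width": config.bin_width,
        "samples": {
            s: {"condition": c, "fragments": f"fragments_{s}.bed"}
            for s, c in config.conditions.items()
        },
        "rna_samples": dict(config.rna_conditions),
        "background_rate": config.background_rate,
        "dispersion": config.dispersion,
        "promoter_flank": config.promoter_flank,
        "genome": [[n, int(l)] for n, l in config.genome.chroms],
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return truth
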