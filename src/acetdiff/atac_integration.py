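"""Partition differential H3K27ac regions against directional ATAC peaks.

Within one direction (e.g. "down": less acetylation vs less accessibility),
ATAC peaks are padded 500 bp on both sides, and any >= 1 bp overlap between an
acetylation region and a padded peak assigns both elements to the "both"
class; unmatched elements fall into the acetylation-only or ATAC-only class.
Up- and down-direction analyses never intermix. The "both" tally can differ
counted from the acetylation side and from the ATAC side (many-to-many
overlaps), so both tallies are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeSpec, GenomicInterval

REGION_CLASSES = (
    "acet_down_only",
    "both_down",
    "atac_down_only",
    "acet_up_only",
    "both_up",
    "atac_up_only",
)

DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class VennCounts:
    """Per-direction overlap tallies between acetylation regions and ATAC peaks."""

    direction: str
    acet_only: int
    both_acet: int  # acetylation regions overlapping >=1 padded peak
    both_atac: int  # ATAC peaks overlapping >=1 acetylation region
    atac_only: int

    @property
    def n_acet(self) -> int:
        return self.acet_only + self.both_acet

    @property
    def n_atac(self) -> int:
        return self.atac_only + self.both_atac


def pad_peaks(
    peaks: list[GenomicInterval], genome: GenomeSpec, pad: int = 500
) -> list[GenomicInterval]:
    """Extend each peak ``pad`` bp up- and downstream, clipped to the chromosome."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    out = []
    for p in peaks:
        length = genome.lengths[p.chrom]
        out.append(
            GenomicInterval(
                p.chrom,
                max(0, p.start - pad),
                min(length, p.end + pad),
                p.strand,
                p.name,
                p.score,
            )
        )
    return out


def _overlap_flags(
    queries: list[GenomicInterval], subjects: list[GenomicInterval]
) -> np.ndarray:
    """For each query, whether any subject overlaps it by >= 1 bp (sorted sweep)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in subjects:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        # merge into disjoint runs so a binary search suffices
        ms, me = [], []
        for st, en in ivs:
            if ms and st <= me[-1]:
                me[-1] = max(me[-1], en)
            else:
                ms.append(st)
                me.append(en)
        merged[chrom] = (np.asarray(ms), np.asarray(me))
    flags = np.zeros(len(queries), dtype=bool)
    for i, qv in enumerate(queries):
        if qv.chrom not in merged:
            continue
        ms, me = merged[qv.chrom]
        k = np.searchsorted(ms, qv.end, "left") - 1
        flags[i] = k >= 0 and me[k] > qv.start
    return flags


def classify_regions(
    acet_regions: list[GenomicInterval],
    atac_peaks: list[GenomicInterval],
    direction: str,
    genome: GenomeSpec,
    pad: int = 500,
) -> tuple[list[str], list[str], VennCounts]:
    """Assign each element of one direction to its overlap class.

    Returns per-acetylation-region classes, per-ATAC-peak classes and the
    Venn tallies. Elements carrying a direction in their ``name`` field must
    match ``direction``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    for iv in list(acet_regions) + list(atac_peaks):
        if iv.name in DIRECTIONS and iv.name != direction:
            raise ValueError(
                f"interval labelled {iv.name!r} passed to {direction!r} analysis"
            )
    padded = pad_peaks(atac_peaks, genome, pad)
    acet_hit = _overlap_flags(acet_regions, padded)
    atac_hit = _overlap_flags(padded, acet_regions)
    both = f"both_{direction}"
    acet_classes = [both if h else f"acet_{direction}_only" for h in acet_hit]
    atac_classes = [both if h else f"atac_{direction}_only" for h in atac_hit]
    venn = VennCounts(
        direction=direction,
        acet_only=int((~acet_hit).sum()),
        both_acet=int(acet_hit.sum()),
        both_atac=int(atac_hit.sum()),
        atac_only=int((~atac_hit).sum()),
    )
    return acet_classes, atac_classes, venn


def summit_windows(
    peaks: list[GenomicInterval], genome: GenomeSpec, width: int = 200
) -> list[GenomicInterval]:
    """Fixed-width windows on peak centres (the stand-in for ATAC summits)."""
    if width <= 0 or width % 2:
        raise ValueError("width must be a positive even number")
    out = []
    for p in peaks:
        length = genome.lengths[p.chrom]
        c = p.center
        out.append(
            GenomicInterval(
                p.chrom,
                max(0, c - width // 2),
                min(length, c + width // 2),
                p.strand,
                p.name,
                p.score,
            )
        )
    return out
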