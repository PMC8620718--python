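"""Genomic data model and file I/O.

All coordinates are 0-based, half-open (BED convention). The GTF-lite gene
table converter translates 1-based GTF starts on read; nothing downstream
ever sees 1-based coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-", ".")
NUCLEOTIDES = "ACGT"


class FormatError(ValueError):
    """A malformed input file (message carries the offending line number)."""


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names and lengths in bp."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


@dataclass
class BinGrid:
    """Fixed-width tiling of a genome; the final bin per chromosome may be short.

    Bins are stored as flat arrays in genomic order (chromosomes in GenomeSpec
    order); ``bin_index`` maps a (chrom, position) pair to its bin.
    """

    genome: GenomeSpec
    bin_width: int
    chrom_idx: np.ndarray = field(repr=False)
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)
    _offsets: dict[str, tuple[int, int]] = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def bin_index(self, chrom: str, pos: int | np.ndarray) -> np.ndarray:
        """Bin id(s) containing 0-based position(s) on ``chrom``."""
        off, nbins = self._offsets[chrom]
        idx = np.asarray(pos) // self.bin_width
        if np.any((idx < 0) | (idx >= nbins)):
            raise ValueError(f"position outside {chrom}")
        return off + idx

    def interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            self.genome.names[self.chrom_idx[i]],
            int(self.starts[i]),
            int(self.ends[i]),
        )

    def to_frame(self):
        import pandas as pd

        names = np.array(self.genome.names)
        return pd.DataFrame(
            {"chrom": names[self.chrom_idx], "start": self.starts, "end": self.ends}
        )


def make_bin_grid(genome: GenomeSpec, bin_width: int = 500) -> BinGrid:
    """Tile every chromosome with ``bin_width`` bins, keeping the final partial bin."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    chrom_idx, starts, ends = [], [], []
    offsets = {}
    off = 0
    for ci, (name, length) in enumerate(genome.chroms):
        n = -(-length // bin_width)  # ceil
        s = np.arange(n, dtype=np.int64) * bin_width
        e = np.minimum(s + bin_width, length)
        chrom_idx.append(np.full(n, ci, dtype=np.int32))
        starts.append(s)
        ends.append(e)
        offsets[name] = (off, n)
        off += n
    return BinGrid(
        genome=genome,
        bin_width=bin_width,
        chrom_idx=np.concatenate(chrom_idx),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        _offsets=offsets,
    )


def promoter_window(
    gene: GeneModel, genome: GenomeSpec, flank: int = 2000
) -> GenomicInterval:
    """Strand-symmetric window [tss-flank, tss+flank) clipped to the chromosome."""
    length = genome.lengths[gene.chrom]
    if not 0 <= gene.tss < length:
        raise ValueError(f"gene {gene.gene_id}: TSS outside {gene.chrom}")
    start = max(0, gene.tss - flank)
    end = min(length, gene.tss + flank)
    return GenomicInterval(gene.chrom, start, end, gene.strand, name=gene.gene_id)


# ---------------------------------------------------------------------------
# chrom.sizes

def read_chrom_sizes(path) -> GenomeSpec:
    chroms = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: length is not an integer") from None
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length for {name}")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise FormatError(f"{path}: no chromosomes")
    return GenomeSpec(tuple(chroms))


def write_chrom_sizes(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chroms:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path, genome: GenomeSpec | None = None) -> list[GenomicInterval]:
    """Read BED3+ records in file order; columns 4-6 become name/score/strand."""
    out = []
    lengths = genome.lengths if genome is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end or start < 0:
                raise FormatError(f"{path}:{lineno}: start must satisfy 0 <= start < end")
            if lengths is not None:
                if chrom not in lengths:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom}")
                if end > lengths[chrom]:
                    raise FormatError(f"{path}:{lineno}: end beyond {chrom} length")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] != ".":
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand != ".":
                fields.append("%g" % iv.score if iv.score is not None else ".")
            if iv.strand != ".":
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene tables

def read_gene_table(path, genome: GenomeSpec | None = None) -> list[GeneModel]:
    """Read a 4-column table: gene_id, chrom, strand, tss (0-based)."""
    genes = []
    seen = set()
    lengths = genome.lengths if genome is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            gene_id, chrom, strand = parts[0], parts[1], parts[2]
            try:
                tss = int(parts[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: TSS is not an integer") from None
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene {gene_id}")
            seen.add(gene_id)
            if lengths is not None:
                if chrom not in lengths:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom}")
                if not 0 <= tss < lengths[chrom]:
                    raise FormatError(f"{path}:{lineno}: TSS outside {chrom}")
            genes.append(GeneModel(gene_id, chrom, strand, tss))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def gtf_to_gene_table(gtf_path, out_path, feature: str = "gene") -> int:
    """Convert GTF ``gene`` records to the 4-column gene table.

    The TSS is the 1-based GTF start converted to 0-based for + strand genes
    and the GTF end minus one for - strand genes. Returns the number of genes
    written.
    """
    genes = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{gtf_path}:{lineno}: expected 9 GTF columns")
            if parts[2] != feature:
                continue
            chrom, start, end, strand, attrs = (
                parts[0], int(parts[3]), int(parts[4]), parts[6], parts[8],
            )
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise FormatError(f"{gtf_path}:{lineno}: missing gene_id attribute")
            tss = start - 1 if strand == "+" else end - 1
            genes.append(GeneModel(gene_id, chrom, strand, tss))
    write_gene_table(genes, out_path)
    return len(genes)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read all sequences into memory, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PWMs (JASPAR-style)

@dataclass(frozen=True)
class PWM:
    """Position probability matrix over A,C,G,T with a background distribution."""

    motif_id: str
    matrix: np.ndarray  # shape (length, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be length x 4")
        if m.shape[0] < 4:
            raise ValueError(f"{self.motif_id}: motif length must be >= 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: rows must sum to 1")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: background must be 4 probabilities")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(NUCLEOTIDES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.background[::-1])


def read_pwm_jaspar(path, background: Sequence[float] | None = None) -> list[PWM]:
    """Read JASPAR-style matrices (``>id`` header, 4 rows ``A [ .. ]``).

    Count matrices are converted to probabilities with a pseudocount of 1 per
    cell; matrices that already hold probabilities (columns summing to ~1) are
    kept as-is.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    motifs: list[PWM] = []
    cur_id = None
    rows: dict[str, list[float]] = {}

    def flush():
        if cur_id is None:
            return
        if set(rows) != set("ACGT"):
            raise FormatError(f"{path}: motif {cur_id}: need exactly rows A,C,G,T")
        lens = {len(v) for v in rows.values()}
        if len(lens) != 1:
            raise FormatError(f"{path}: motif {cur_id}: ragged matrix")
        mat = np.array([rows[n] for n in NUCLEOTIDES], float).T  # (L, 4)
        col_sums = mat.sum(axis=1)
        if np.any(col_sums <= 0):
            raise FormatError(f"{path}: motif {cur_id}: column of zeros")
        if np.allclose(col_sums, 1.0, atol=1e-3):
            mat = mat / col_sums[:, None]
        else:  # counts: pseudocount 1
            mat = (mat + 1.0) / (col_sums + 4.0)[:, None]
        motifs.append(PWM(cur_id, mat, bg))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0]
                rows = {}
            else:
                parts = line.replace("[", " ").replace("]", " ").split()
                if parts and parts[0].upper() in "ACGT" and len(parts[0]) == 1:
                    nt, values = parts[0].upper(), parts[1:]
                elif cur_id is not None and len(rows) < 4:
                    nt = "ACGT"[len(rows)]
                    values = parts
                else:
                    raise FormatError(f"{path}:{lineno}: unparsable matrix row")
                try:
                    rows[nt] = [float(v) for v in values]
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric matrix entry") from None
    flush()
    return motifs


def write_pwm_jaspar(motifs: Iterable[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in motifs:
            fh.write(f">{pwm.motif_id}\n")
            for i, nt in enumerate(NUCLEOTIDES):
                vals = " ".join("%.6f" % v for v in pwm.matrix[:, i])
                fh.write(f"{nt} [ {vals} ]\n")
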