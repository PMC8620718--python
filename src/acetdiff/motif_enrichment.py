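"""PWM scanning and per-class motif enrichment with a GC-matched background.

Scanning is a plain log-odds scan of both strands: a position is a hit when
its score reaches ``score_fraction`` of the maximum achievable score of the
matrix. Enrichment compares the fraction of target windows containing >= 1
hit against GC-matched background windows with a one-sided binomial tail; a
motif is called enriched in a class when p < 1e-10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import PWM, GenomicInterval

ENRICHMENT_ALPHA = 1e-10
DEFAULT_SCORE_FRACTION = 0.8

_ENCODE = np.full(256, 4, dtype=np.int8)
for i, nt in enumerate("ACGT"):
    _ENCODE[ord(nt)] = i
    _ENCODE[ord(nt.lower())] = i

_NEG = -1e9  # effective -inf for N positions


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _logodds(pwm: PWM) -> np.ndarray:
    """(length, 5) log-odds table; column 4 scores N as -inf."""
    table = np.log(np.maximum(pwm.matrix, 1e-9) / pwm.background)
    return np.hstack([table, np.full((len(pwm), 1), _NEG)])


def _window_scores(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    m = table.shape[0]
    if codes.size < m:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, m)
    return table[np.arange(m), win].sum(axis=1)


def pwm_scan(
    sequence: str, pwm: PWM, score_fraction: float = DEFAULT_SCORE_FRACTION
) -> list[tuple[int, str, float]]:
    """Hits (position, strand, score) on both strands of ``sequence``.

    A hit scores at least ``score_fraction`` times the maximum achievable
    log-odds of the matrix; the position is the leftmost base of the matched
    window on the forward strand for either strand. Sequences shorter than
    the motif yield no hits.
    """
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    codes = encode_sequence(sequence)
    fwd = _logodds(pwm)
    rev = _logodds(pwm.reverse_complement())
    threshold = score_fraction * fwd[:, :4].max(axis=1).sum()
    hits = []
    for strand, table in (("+", fwd), ("-", rev)):
        scores = _window_scores(codes, table)
        for pos in np.nonzero(scores >= threshold)[0]:
            hits.append((int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def has_hit(
    sequence: str, pwm: PWM, score_fraction: float = DEFAULT_SCORE_FRACTION
) -> bool:
    codes = encode_sequence(sequence)
    fwd = _logodds(pwm)
    threshold = score_fraction * fwd[:, :4].max(axis=1).sum()
    for table in (fwd, _logodds(pwm.reverse_complement())):
        scores = _window_scores(codes, table)
        if scores.size and scores.max() >= threshold:
            return True
    return False


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    codes = encode_sequence(seq)
    return float(np.isin(codes, (1, 2)).mean())


def window_sequence(window: GenomicInterval, sequences: dict[str, str]) -> str:
    return sequences[window.chrom][window.start : window.end]


def select_background(
    target_windows: list[GenomicInterval],
    pool_windows: list[GenomicInterval],
    sequences: dict[str, str],
    ratio: int = 2,
    gc_tol: float = 0.02,
    seed: int = 0,
) -> list[GenomicInterval]:
    """GC-matched background: up to ``ratio`` pool windows per target.

    Pool windows overlapping any target are dropped first; matching is by
    |GC(pool) - GC(target)| <= gc_tol, sampled without replacement with a
    seeded generator. Targets that cannot be fully matched are reported in a
    warning.
    """
    if not pool_windows:
        raise ValueError("empty background pool")
    pool = [
        w for w in pool_windows if not any(w.overlaps(t) for t in target_windows)
    ]
    if not pool:
        raise ValueError("background pool is entirely overlapped by targets")
    rng = np.random.default_rng(seed)
    pool_gc = np.array([gc_fraction(window_sequence(w, sequences)) for w in pool])
    available = np.ones(len(pool), dtype=bool)
    chosen: list[GenomicInterval] = []
    unmatched = []
    for t in target_windows:
        tgc = gc_fraction(window_sequence(t, sequences))
        eligible = np.nonzero(available & (np.abs(pool_gc - tgc) <= gc_tol))[0]
        take = min(ratio, eligible.size)
        if take < ratio:
            unmatched.append(t.name or f"{t.chrom}:{t.start}-{t.end}")
        if take:
            picked = rng.choice(eligible, size=take, replace=False)
            available[picked] = False
            chosen.extend(pool[i] for i in picked)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} target window(s) not fully GC-matched: "
            + ", ".join(unmatched[:10]),
            stacklevel=2,
        )
    return chosen


@dataclass(frozen=True)
class MotifEnrichment:
    motif_id: str
    region_class: str
    n_target: int
    k_target: int
    n_background: int
    k_background: int
    p0: float
    p: float
    enriched: bool

    def __post_init__(self):
        if not (0 <= self.k_target <= self.n_target):
            raise ValueError("k_target out of range")
        if not (0 <= self.k_background <= self.n_background):
            raise ValueError("k_background out of range")


def enrichment_test(
    target_seqs: list[str],
    background_seqs: list[str],
    pwm: PWM,
    score_fraction: float = DEFAULT_SCORE_FRACTION,
    region_class: str = "",
    alpha: float = ENRICHMENT_ALPHA,
) -> MotifEnrichment:
    """One-sided binomial enrichment of windows-with-hit vs background rate.

    The background hit probability is pseudocounted,
    p0 = (k_bg + 1) / (n_bg + 2), and p = P(X >= k_target | n_target, p0).
    """
    if not target_seqs or not background_seqs:
        raise ValueError("need at least one target and one background window")
    k_t = sum(has_hit(s, pwm, score_fraction) for s in target_seqs)
    k_b = sum(has_hit(s, pwm, score_fraction) for s in background_seqs)
    n_t, n_b = len(target_seqs), len(background_seqs)
    p0 = (k_b + 1) / (n_b + 2)
    p = float(stats.binom.sf(k_t - 1, n_t, p0))
    return MotifEnrichment(
        motif_id=pwm.motif_id,
        region_class=region_class,
        n_target=n_t,
        k_target=int(k_t),
        n_background=n_b,
        k_background=int(k_b),
        p0=float(p0),
        p=p,
        enriched=bool(p < alpha),
    )


def per_class_enrichment(
    class_windows: dict[str, list[GenomicInterval]],
    pool_windows: list[GenomicInterval],
    motif_library: list[PWM],
    sequences: dict[str, str],
    score_fraction: float = DEFAULT_SCORE_FRACTION,
    ratio: int = 2,
    gc_tol: float = 0.02,
    seed: int = 0,
    alpha: float = ENRICHMENT_ALPHA,
) -> pd.DataFrame:
    """Test every (class, motif) pair; classes without windows are skipped.

    Each class gets its own GC-matched background drawn from the pool with a
    deterministic per-class seed offset; rows are sorted by p within class.
    """
    rows = []
    for ci, (cls, windows) in enumerate(sorted(class_windows.items())):
        if not windows:
            warnings.warn(f"class {cls} has no windows; skipped", stacklevel=2)
            continue
        background = select_background(
            windows, pool_windows, sequences, ratio, gc_tol, seed=seed * 1000 + ci
        )
        target_seqs = [window_sequence(w, sequences) for w in windows]
        background_seqs = [window_sequence(w, sequences) for w in background]
        for pwm in motif_library:
            r = enrichment_test(
                target_seqs, background_seqs, pwm, score_fraction, cls, alpha
            )
            rows.append(dataclass_to_row(r))
    df = pd.DataFrame(
        rows,
        columns=[
            "region_class", "motif_id", "n_target", "k_target",
            "n_background", "k_background", "p0", "p", "enriched",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["region_class", "p", "motif_id"], kind="mergesort", ignore_index=True
        )
    return df


def dataclass_to_row(r: MotifEnrichment) -> dict:
    return dict(
        region_class=r.region_class,
        motif_id=r.motif_id,
        n_target=r.n_target,
        k_target=r.k_target,
        n_background=r.n_background,
        k_background=r.k_background,
        p0=r.p0,
        p=r.p,
        enriched=r.enriched,
    )


# ---------------------------------------------------------------------------
# built-in motif models

def _soft_matrix(pattern: str) -> np.ndarray:
    """Probability matrix from an IUPAC-ish consensus (supports S, W, R, Y)."""
    degenerate = {
        "S": "CG", "W": "AT", "R": "AG", "Y": "CT",
    }
    rows = []
    for ch in pattern:
        row = np.full(4, 0.01)
        if ch in "ACGT":
            row["ACGT".index(ch)] = 0.97
        elif ch in degenerate:
            row[:] = 0.015
            for nt in degenerate[ch]:
                row["ACGT".index(nt)] = 0.485
        else:
            raise ValueError(f"unsupported consensus letter {ch}")
        rows.append(row / row.sum())
    return np.array(rows)


def default_motif_library(background=None) -> list[PWM]:
    """Built-in motif models for the transcription-factor families of interest.

    AP-1 (Jun/Fos TGASTCA), MEF2 (CTAWWWWTAG), a PPAR/RXR-like DR1 direct
    repeat (AGGTCAAAGGTCA) and a KLF/SP GC-box (GGGGCGGGG).
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    motifs = {
        "AP1": "TGASTCA",
        "MEF2": "CTAWWWWTAG",
        "PPAR_RXR": "AGGTCAAAGGTCA",
        "KLF": "GGGGCGGGG",
    }
    return [PWM(mid, _soft_matrix(pat), bg) for mid, pat in motifs.items()]
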