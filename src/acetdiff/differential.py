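"""Negative-binomial two-group testing, BH-FDR and region merging.

The test models counts as NB with variance mu + alpha*mu^2. Per-feature
dispersions are estimated by method of moments from the pooled within-group
variance and then shrunk toward a robust across-feature prior (5%-trimmed
mean over features with mean >= 10) with prior weight ``prior_df``, in the
spirit of limma's empirical-Bayes variance moderation. The Wald statistic
log2FC / SE(log2FC) — SE from the NB delta method at the fitted group means,
with a pseudo-mean of 0.5 — is referred to a Student t distribution with
(n1 + n2 - 2) + prior_df degrees of freedom. At three replicates per group
this combination is what keeps the null p-value distribution uniform while
retaining power; a normal reference on unmoderated method-of-moments
dispersions is badly anti-conservative there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PRIOR_DF = 12
DEFAULT_ALPHA_FLOOR = 0.01
_PRIOR_MEAN_MIN = 10.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    The reference is the per-feature geometric mean over samples; only
    features positive in every sample enter the median.
    """
    X = counts.to_numpy(dtype=float)
    positive = (X > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature with positive counts in all samples")
    logX = np.log(X[positive])
    log_geo = logX.mean(axis=1)
    factors = np.exp(np.median(logX - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_arrays(counts: pd.DataFrame, conditions: dict[str, str]):
    ctrl = [s for s in counts.columns if conditions[s] == "control"]
    case = [s for s in counts.columns if conditions[s] == "case"]
    if not ctrl or not case:
        raise ValueError("need samples in both conditions")
    return counts[ctrl].to_numpy(float), counts[case].to_numpy(float)


def _moments(c1: np.ndarray, c2: np.ndarray):
    n1, n2 = c1.shape[1], c2.shape[1]
    m1, m2 = c1.mean(axis=1), c2.mean(axis=1)
    d = n1 + n2 - 2
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group to estimate dispersion")
    v = (c1.var(axis=1, ddof=1) * (n1 - 1) + c2.var(axis=1, ddof=1) * (n2 - 1)) / d
    mall = np.concatenate([c1, c2], axis=1).mean(axis=1)
    raw_alpha = (v - mall) / np.maximum(mall, 1e-12) ** 2
    return m1, m2, v, mall, raw_alpha, d


def estimate_dispersion(
    counts: pd.DataFrame,
    conditions: dict[str, str],
    size_factors: pd.Series | None = None,
    floor: float = DEFAULT_ALPHA_FLOOR,
) -> pd.Series:
    """Per-feature method-of-moments NB dispersion, floored at ``floor``."""
    X = counts if size_factors is None else counts / size_factors
    c1, c2 = _group_arrays(X, conditions)
    _, _, _, _, raw_alpha, _ = _moments(c1, c2)
    return pd.Series(
        np.maximum(raw_alpha, floor), index=counts.index, name="dispersion"
    )


def _moderated_dispersion(
    raw_alpha: np.ndarray,
    mall: np.ndarray,
    d: int,
    prior_df: int,
    floor: float,
) -> tuple[np.ndarray, float]:
    informative = mall >= _PRIOR_MEAN_MIN
    vals = raw_alpha[informative] if informative.any() else raw_alpha
    prior = float(stats.trim_mean(vals, 0.05)) if vals.size else floor
    prior = max(prior, 0.0)
    moderated = (d * raw_alpha + prior_df * prior) / (d + prior_df)
    return np.maximum(moderated, floor), prior


def nb_wald_test(
    counts: pd.DataFrame,
    conditions: dict[str, str],
    size_factors: pd.Series | None = None,
    prior_df: int = DEFAULT_PRIOR_DF,
    alpha_floor: float = DEFAULT_ALPHA_FLOOR,
) -> pd.DataFrame:
    """Per-feature moderated NB Wald test of case vs control.

    Returns base_mean, log2fc (case over control, pseudo-mean 0.5), se,
    dispersion (moderated), stat and p. No multiple-testing adjustment here.
    """
    X = counts if size_factors is None else counts / size_factors
    c1, c2 = _group_arrays(X, conditions)
    if c1.sum() == 0 or c2.sum() == 0:
        raise ValueError("a condition has all-zero counts for every feature")
    n1, n2 = c1.shape[1], c2.shape[1]
    m1, m2, v, mall, raw_alpha, d = _moments(c1, c2)
    alpha, prior = _moderated_dispersion(raw_alpha, mall, d, prior_df, alpha_floor)
    log2fc = np.log2((m2 + 0.5) / (m1 + 0.5))
    se = (
        np.sqrt((1.0 / (m1 + 0.5) + alpha) / n1 + (1.0 / (m2 + 0.5) + alpha) / n2)
        / np.log(2)
    )
    se = np.maximum(se, 1e-12)
    stat = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(stat), df=d + prior_df)
    out = pd.DataFrame(
        {
            "base_mean": mall,
            "log2fc": log2fc,
            "se": se,
            "dispersion": alpha,
            "stat": stat,
            "p": p,
        },
        index=counts.index,
    )
    out.attrs["dispersion_prior"] = prior
    out.attrs["df"] = d + prior_df
    return out


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def finalize_results(
    results: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Attach BH q-values, significance flags and direction labels."""
    out = results.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    direction = np.where(
        out["significant"] & (out["log2fc"] > 0),
        "up",
        np.where(out["significant"] & (out["log2fc"] < 0), "down", "ns"),
    )
    out["direction"] = direction
    return out


def drop_all_zero(
    features: pd.DataFrame, counts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove features with zero counts in every sample (before testing/BH)."""
    keep = counts.sum(axis=1) > 0
    return features.loc[keep.to_numpy()], counts.loc[keep]


def merge_significant_bins(
    bin_results: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Merge maximal runs of adjacent, same-direction significant bins.

    ``bin_results`` must carry chrom/start/end in genomic order plus q and
    log2fc; bins are adjacent when one starts where the previous one ends on
    the same chromosome. Regions report their span, direction, constituent
    bin count, mean log2FC and minimum q.
    """
    req = {"chrom", "start", "end", "q", "log2fc"}
    if not req.issubset(bin_results.columns):
        raise ValueError(f"bin results need columns {sorted(req)}")
    chrom = bin_results["chrom"].to_numpy()
    start = bin_results["start"].to_numpy(np.int64)
    end = bin_results["end"].to_numpy(np.int64)
    for c in np.unique(chrom):
        s = start[chrom == c]
        e = end[chrom == c]
        if np.any(np.diff(s) <= 0) or np.any(s >= e) or np.any(s[1:] < e[:-1]):
            raise ValueError("bins must be non-overlapping and genomically sorted")
    q = bin_results["q"].to_numpy(float)
    lfc = bin_results["log2fc"].to_numpy(float)
    sig = q < q_threshold
    sign = np.sign(lfc)

    rows = []
    i, n = 0, len(bin_results)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and sig[j + 1]
            and chrom[j + 1] == chrom[i]
            and start[j + 1] == end[j]
            and sign[j + 1] == sign[i]
        ):
            j += 1
        seg = slice(i, j + 1)
        qmin = float(q[seg].min())
        rows.append(
            dict(
                chrom=chrom[i],
                start=int(start[i]),
                end=int(end[j]),
                direction="up" if sign[i] > 0 else "down",
                n_bins=j - i + 1,
                mean_log2fc=float(lfc[seg].mean()),
                q_min=qmin,
                score=float(-10.0 * np.log10(max(qmin, 1e-300))),
            )
        )
        i = j + 1
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "direction", "n_bins",
            "mean_log2fc", "q_min", "score",
        ],
    )


def promoter_counts(
    fragments_by_sample: dict[str, pd.DataFrame],
    genes,
    genome,
    flank: int = 2000,
) -> pd.DataFrame:
    """Fragment-midpoint counts in TSS +/- flank windows, per gene per sample.

    Windows may overlap; a fragment then counts toward every window covering
    its midpoint.
    """
    from .genome_io import promoter_window

    windows = [promoter_window(g, genome, flank) for g in genes]
    cols = {}
    for sample, frags in fragments_by_sample.items():
        mids_by_chrom = {
            chrom: np.sort(
                (
                    sub["start"].to_numpy(np.int64)
                    + sub["end"].to_numpy(np.int64)
                )
                // 2
            )
            for chrom, sub in frags.groupby("chrom", sort=False)
        }
        counts = np.zeros(len(windows), dtype=np.int64)
        for i, w in enumerate(windows):
            mids = mids_by_chrom.get(w.chrom)
            if mids is None:
                continue
            counts[i] = np.searchsorted(mids, w.end, "left") - np.searchsorted(
                mids, w.start, "left"
            )
        cols[sample] = counts
    return pd.DataFrame(cols, index=pd.Index([g.gene_id for g in genes], name="gene_id"))


def promoter_differential(
    fragments_by_sample: dict[str, pd.DataFrame],
    genes,
    genome,
    conditions: dict[str, str],
    flank: int = 2000,
    background_threshold: int = 20,
    q_threshold: float = 0.05,
    prior_df: int = DEFAULT_PRIOR_DF,
) -> pd.DataFrame:
    """Promoter-window differential acetylation per gene.

    Same chain as bins: count, background-subtract, quantile-normalize,
    round, moderated NB test, BH. Genes with no fragments in any sample are
    reported untested (NA statistics).
    """
    from .binning_signal import (
        estimate_background,
        quantile_normalize,
        subtract_background,
    )

    raw = promoter_counts(fragments_by_sample, genes, genome, flank)
    tested_mask = raw.sum(axis=1) > 0
    tested = raw.loc[tested_mask]
    out_cols = ["base_mean", "log2fc", "se", "dispersion", "stat", "p", "q",
                "significant", "direction"]
    if tested.empty:
        res = pd.DataFrame(index=raw.index, columns=out_cols)
        res["tested"] = False
        return res
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # high-signal windows: background may be 0
        sub = pd.DataFrame(
            {
                s: subtract_background(
                    tested[s].to_numpy(),
                    estimate_background(tested[s].to_numpy(), background_threshold),
                )
                for s in tested.columns
            },
            index=tested.index,
        )
    normed = quantile_normalize(sub)
    rounded = pd.DataFrame(
        np.rint(normed.to_numpy()), index=normed.index, columns=normed.columns
    )
    res = finalize_results(
        nb_wald_test(rounded, conditions, prior_df=prior_df), q_threshold
    )
    full = res.reindex(raw.index)
    full["tested"] = tested_mask
    full.loc[~tested_mask, "significant"] = False
    full.loc[~tested_mask, "direction"] = "ns"
    return full
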