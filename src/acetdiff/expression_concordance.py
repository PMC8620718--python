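"""Differential expression and promoter-acetylation concordance.

A differentially expressed gene is *concordant* when its promoter window is
also significantly differentially acetylated in the same direction, and
*discordant* when the directions disagree; DE genes with an unchanged
promoter are labelled accordingly, and genes missing from (or untested in)
the promoter analysis are *not-tested*. "Directly correlated" is
operationalized as sign agreement of significant changes; a Spearman
correlation of the two log2 fold changes over doubly-significant genes is
reported as a descriptive statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import (
    DEFAULT_PRIOR_DF,
    finalize_results,
    nb_wald_test,
    size_factors,
)

CONCORDANCE_LABELS = (
    "concordant",
    "discordant",
    "acetylation-unchanged",
    "not-tested",
)


def de_genes(
    expression_counts: pd.DataFrame,
    conditions: dict[str, str],
    q_threshold: float = 0.05,
    prior_df: int = DEFAULT_PRIOR_DF,
) -> pd.DataFrame:
    """Moderated NB Wald test per gene on raw counts (median-of-ratios SFs).

    Genes with zero counts in every sample are excluded before testing and
    before BH fixes the number of tests.
    """
    keep = expression_counts.sum(axis=1) > 0
    counts = expression_counts.loc[keep]
    sf = size_factors(counts)
    res = nb_wald_test(counts, conditions, size_factors=sf, prior_df=prior_df)
    return finalize_results(res, q_threshold)


def concordance(
    de_table: pd.DataFrame,
    promoter_table: pd.DataFrame,
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Label every DE-significant gene by promoter-acetylation agreement.

    Both tables are indexed by gene_id and carry log2fc and q. Returns the
    per-gene records and a summary with label counts, the concordance
    fraction concordant / (concordant + discordant), and the Spearman
    correlation of the two log2FCs among doubly-significant genes.
    """
    sig = de_table[de_table["q"] < q_threshold]
    prom_tested = promoter_table
    if "tested" in promoter_table.columns:
        prom_tested = promoter_table[promoter_table["tested"].astype(bool)]
    rows = []
    for gene_id, de_row in sig.iterrows():
        rec = dict(
            gene_id=gene_id,
            expression_log2fc=de_row["log2fc"],
            expression_q=de_row["q"],
            promoter_log2fc=np.nan,
            promoter_q=np.nan,
        )
        if gene_id not in prom_tested.index:
            rec["label"] = "not-tested"
        else:
            prow = prom_tested.loc[gene_id]
            rec["promoter_log2fc"] = prow["log2fc"]
            rec["promoter_q"] = prow["q"]
            if prow["q"] >= q_threshold:
                rec["label"] = "acetylation-unchanged"
            elif np.sign(prow["log2fc"]) == np.sign(de_row["log2fc"]):
                rec["label"] = "concordant"
            else:
                rec["label"] = "discordant"
        rows.append(rec)
    records = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "expression_log2fc", "expression_q",
            "promoter_log2fc", "promoter_q", "label",
        ],
    )
    counts = {label: 0 for label in CONCORDANCE_LABELS}
    if len(records):
        counts.update(records["label"].value_counts().to_dict())
    n_conc, n_disc = counts["concordant"], counts["discordant"]
    both_sig = records[records["label"].isin(["concordant", "discordant"])]
    if len(both_sig) >= 3:
        rho = float(
            stats.spearmanr(
                both_sig["expression_log2fc"], both_sig["promoter_log2fc"]
            ).statistic
        )
    else:
        rho = float("nan")
    summary = {
        "n_de_significant": int(len(sig)),
        **{f"n_{k}": int(v) for k, v in counts.items()},
        "concordance_fraction": (
            n_conc / (n_conc + n_disc) if (n_conc + n_disc) else float("nan")
        ),
        "spearman_log2fc": rho,
    }
    return records, summary
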