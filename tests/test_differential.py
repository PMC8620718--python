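import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acetdiff.differential import (
    bh_adjust,
    estimate_dispersion,
    finalize_results,
    merge_significant_bins,
    nb_wald_test,
    promoter_differential,
    size_factors,
)
from acetdiff.genome_io import GeneModel, GenomeSpec

from conftest import nb_counts


def bh_oracle(p):
    """Literal BH definition: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            1.0,
            min(
                p[order[j - 1]] * m / j
                for j in range(rank_i, m + 1)
            ),
        )
    return q


def merge_oracle(chrom, start, end, q, lfc, threshold):
    """Linear scan collecting maximal significant same-sign adjacent runs."""
    regions = []
    current = None
    for i in range(len(q)):
        sig = q[i] < threshold
        sign = np.sign(lfc[i])
        if not sig:
            current = None
            continue
        if (
            current is not None
            and current["chrom"] == chrom[i]
            and current["end"] == start[i]
            and current["sign"] == sign
        ):
            current["end"] = end[i]
            current["n"] += 1
        else:
            current = dict(chrom=chrom[i], start=start[i], end=end[i], sign=sign, n=1)
            regions.append(current)
    return [(r["chrom"], r["start"], r["end"], r["sign"], r["n"]) for r in regions]


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        c = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(size_factors(c), [1.0, 1.0])

    def test_doubled_sample_median_of_ratios(self):
        c = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        np.testing.assert_allclose(
            size_factors(c), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_rows_with_zeros_excluded_from_median(self):
        c = pd.DataFrame({"a": [10, 20, 0], "b": [10, 20, 50]})
        np.testing.assert_allclose(size_factors(c), [1.0, 1.0])

    def test_all_rows_contain_zero_rejected(self):
        c = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="positive"):
            size_factors(c)


class TestDispersion:
    def test_poisson_counts_hit_the_floor(self, rng):
        X = nb_counts(rng, np.full(2000, 100.0), 0.0, 10)
        cols = [f"control_{i}" for i in range(5)] + [f"case_{i}" for i in range(5)]
        counts = pd.DataFrame(X, columns=cols)
        cond = {c: ("control" if "control" in c else "case") for c in cols}
        disp = estimate_dispersion(counts, cond)
        assert (disp == 0.01).mean() > 0.5

    def test_recovers_simulated_dispersion_at_large_n(self, rng):
        X = nb_counts(rng, np.full(300, 100.0), 0.2, 100)
        cols = [f"control_{i}" for i in range(50)] + [f"case_{i}" for i in range(50)]
        counts = pd.DataFrame(X, columns=cols)
        cond = {c: ("control" if "control" in c else "case") for c in cols}
        assert 0.1 <= estimate_dispersion(counts, cond).median() <= 0.3

    def test_constant_feature_floored(self):
        counts = pd.DataFrame(
            {f"s{i}": [50, 7] for i in range(6)}
        )
        cond = {f"s{i}": ("control" if i < 3 else "case") for i in range(6)}
        assert (estimate_dispersion(counts, cond) == 0.01).all()


class TestNBWaldTest:
    def test_identical_groups_are_null(self):
        counts = pd.DataFrame(
            {"c1": [10, 50], "c2": [12, 40], "a1": [10, 50], "a2": [12, 40]}
        )
        cond = {"c1": "control", "c2": "control", "a1": "case", "a2": "case"}
        res = nb_wald_test(counts, cond)
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_planted_fourfold_log2fc_recovered(self, rng):
        mu = np.full(2000, 100.0)
        ctrl = nb_counts(rng, mu, 0.05, 3)
        case = nb_counts(rng, mu * 4, 0.05, 3)
        counts = pd.DataFrame(
            np.hstack([ctrl, case]),
            columns=["c1", "c2", "c3", "a1", "a2", "a3"],
        )
        cond = dict.fromkeys(["c1", "c2", "c3"], "control") | dict.fromkeys(
            ["a1", "a2", "a3"], "case"
        )
        res = nb_wald_test(counts, cond)
        assert abs(res["log2fc"].median() - 2.0) < 0.3

    def test_label_swap_negates_log2fc_keeps_p(self, two_group_counts):
        counts, cond = two_group_counts
        res = nb_wald_test(counts, cond)
        swapped = {
            s: ("case" if c == "control" else "control") for s, c in cond.items()
        }
        res2 = nb_wald_test(counts, swapped)
        np.testing.assert_allclose(res2["log2fc"], -res["log2fc"], atol=1e-12)
        np.testing.assert_allclose(res2["p"], res["p"], atol=1e-12)

    def test_all_zero_condition_rejected(self):
        counts = pd.DataFrame(
            {"c1": [0, 0], "c2": [0, 0], "a1": [5, 1], "a2": [3, 2]}
        )
        cond = {"c1": "control", "c2": "control", "a1": "case", "a2": "case"}
        with pytest.raises(ValueError, match="all-zero"):
            nb_wald_test(counts, cond)

    def test_direction_labels_follow_sign_and_significance(self, rng):
        mu = np.full(50, 200.0)
        ctrl = nb_counts(rng, mu, 0.01, 3)
        case = nb_counts(rng, mu * np.where(np.arange(50) < 25, 8.0, 1 / 8), 0.01, 3)
        counts = pd.DataFrame(
            np.hstack([ctrl, case]), columns=["c1", "c2", "c3", "a1", "a2", "a3"]
        )
        cond = dict.fromkeys(["c1", "c2", "c3"], "control") | dict.fromkeys(
            ["a1", "a2", "a3"], "case"
        )
        res = finalize_results(nb_wald_test(counts, cond), 0.05)
        sig = res[res["significant"]]
        assert ((sig["log2fc"] > 0) == (sig["direction"] == "up")).all()


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_saturated(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 100_000), st.integers(1, 60))
    def test_matches_brute_force_definition(self, seed, n):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(size=n), 3)  # rounding provokes ties
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestMergeBins:
    @staticmethod
    def bins_frame(q, lfc, width=500, chrom="chr1"):
        n = len(q)
        return pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "start": np.arange(n) * width,
                "end": (np.arange(n) + 1) * width,
                "q": q,
                "log2fc": lfc,
            }
        )

    def test_two_adjacent_up_bins_merge(self):
        out = merge_significant_bins(
            self.bins_frame([0.01, 0.01, 0.9], [1.0, 1.5, 0.1])
        )
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.start, row.end, row.direction, row.n_bins) == (0, 1000, "up", 2)
        assert row.mean_log2fc == pytest.approx(1.25)

    def test_opposite_signs_split(self):
        out = merge_significant_bins(
            self.bins_frame([0.01, 0.01], [1.0, -1.0])
        )
        assert list(out["direction"]) == ["up", "down"]

    def test_gap_splits_regions(self):
        out = merge_significant_bins(
            self.bins_frame([0.01, 0.9, 0.01], [1.0, 1.0, 1.0])
        )
        assert len(out) == 2

    def test_chromosome_boundary_never_merges(self):
        df = pd.concat(
            [
                self.bins_frame([0.01], [1.0], chrom="chr1"),
                self.bins_frame([0.01], [1.0], chrom="chr2"),
            ],
            ignore_index=True,
        )
        assert len(merge_significant_bins(df)) == 2

    def test_rejects_unsorted_bins(self):
        df = self.bins_frame([0.01, 0.01], [1.0, 1.0]).iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            merge_significant_bins(df)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 100_000), st.integers(1, 80))
    def test_matches_linear_scan_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        q = rng.choice([0.01, 0.5], size=n)
        lfc = rng.choice([-1.0, 1.0], size=n)
        df = self.bins_frame(q, lfc)
        got = merge_significant_bins(df)
        expected = merge_oracle(
            df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy(),
            q, lfc, 0.05,
        )
        assert [
            (r.chrom, r.start, r.end, 1.0 if r.direction == "up" else -1.0, r.n_bins)
            for r in got.itertuples()
        ] == expected

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_covered_bases_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        df = self.bins_frame(rng.uniform(size=n), rng.normal(size=n))
        covered = [
            (merge_significant_bins(df, t)["end"] - merge_significant_bins(df, t)["start"]).sum()
            for t in (0.01, 0.05, 0.2, 0.8)
        ]
        assert covered == sorted(covered)


class TestPromoterDifferential:
    @staticmethod
    def fragments_for(genome, rng, mean_per_sample, region):
        chrom, start, end = region
        out = {}
        for sample, mean in mean_per_sample.items():
            n = rng.poisson(mean)
            s = rng.integers(start, end - 150, size=n)
            out[sample] = pd.DataFrame(
                {"chrom": chrom, "start": s, "end": s + 150}
            )
        return out

    def test_gene_without_fragments_reported_untested(self, small_genome, rng):
        genes = [
            GeneModel("hit", "chr1", "+", 5000),
            GeneModel("empty", "chr2", "+", 3000),
        ]
        frags = self.fragments_for(
            small_genome, rng,
            {"c1": 200, "c2": 200, "a1": 200, "a2": 200},
            ("chr1", 3000, 7000),
        )
        cond = {"c1": "control", "c2": "control", "a1": "case", "a2": "case"}
        res = promoter_differential(frags, genes, small_genome, cond)
        assert not res.loc["empty", "tested"]
        assert np.isnan(res.loc["empty", "p"])
        assert res.loc["hit", "tested"]

    def test_shared_tss_gives_identical_statistics(self, small_genome, rng):
        genes = [
            GeneModel("g1", "chr1", "+", 5000),
            GeneModel("g2", "chr1", "-", 5000),
        ]
        frags = self.fragments_for(
            small_genome, rng,
            {"c1": 300, "c2": 300, "a1": 300, "a2": 300},
            ("chr1", 2000, 8000),
        )
        cond = {"c1": "control", "c2": "control", "a1": "case", "a2": "case"}
        res = promoter_differential(frags, genes, small_genome, cond)
        for col in ("base_mean", "log2fc", "p", "q"):
            assert res.loc["g1", col] == res.loc["g2", col]

    def test_planted_promoter_gain_called_up(self, rng):
        # varied stable baselines: quantile normalization preserves signal
        # only relative to a rank backdrop, as in real promoter landscapes
        n_genes = 30
        genome = GenomeSpec((("chr1", 5000 * n_genes + 4000),))
        genes = [
            GeneModel(f"g{i}", "chr1", "+", 2000 + 5000 * i) for i in range(n_genes)
        ]
        base = np.exp(rng.normal(np.log(300), 0.8, size=n_genes))
        frags = {s: [] for s in ["c1", "c2", "c3", "a1", "a2", "a3"]}
        for i, g in enumerate(genes):
            case_mean = base[i] * (4.0 if i == 0 else 1.0)
            region = (g.tss - 2000, g.tss + 2000)
            for s, mean in [("c1", base[i]), ("c2", base[i]), ("c3", base[i]),
                            ("a1", case_mean), ("a2", case_mean), ("a3", case_mean)]:
                n = rng.poisson(mean)
                starts = rng.integers(region[0], region[1] - 150, size=n)
                frags[s].append(
                    pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 150})
                )
        frags = {s: pd.concat(v, ignore_index=True) for s, v in frags.items()}
        cond = dict.fromkeys(["c1", "c2", "c3"], "control") | dict.fromkeys(
            ["a1", "a2", "a3"], "case"
        )
        res = promoter_differential(frags, genes, genome, cond)
        assert res.loc["g0", "direction"] == "up" and res.loc["g0", "q"] < 0.05


class TestDeseq2CrossCheck:
    def test_log2fc_agrees_with_deseq2_reference(self, rng):
        """Independent route: DESeq2 (pydeseq2) on the same counts should
        produce closely correlated fold-change estimates and matching signs
        for strong effects."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        mu = np.exp(rng.normal(np.log(150), 1.0, 200))
        fold = np.ones(200)
        fold[:40] = 4.0
        fold[40:80] = 0.25
        ctrl = nb_counts(rng, mu, 0.05, 3)
        case = nb_counts(rng, mu * fold, 0.05, 3)
        X = np.hstack([ctrl, case])
        cols = ["c1", "c2", "c3", "a1", "a2", "a3"]
        counts = pd.DataFrame(X, columns=cols)
        cond = dict.fromkeys(cols[:3], "control") | dict.fromkeys(cols[3:], "case")

        sf = size_factors(counts)
        ours = nb_wald_test(counts, cond, size_factors=sf)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=counts.T,
                metadata=pd.DataFrame(
                    {"condition": [cond[c] for c in cols]}, index=cols
                ),
                design="~condition",
                quiet=True,
            )
            dds.deseq2()
            stats_ = DeseqStats(
                dds, contrast=["condition", "case", "control"], quiet=True
            )
            stats_.summary()
        ref = stats_.results_df.reset_index(drop=True)

        r = np.corrcoef(ours["log2fc"], ref["log2FoldChange"])[0, 1]
        assert r > 0.95
        planted = np.arange(80)
        assert (
            np.sign(ours["log2fc"].to_numpy()[planted])
            == np.sign(ref["log2FoldChange"].to_numpy()[planted])
        ).all()
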