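"""Survival profiling: aggregation, normalization, exact testing, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from tldkit import tnseq


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestAggregateFootprints:
    def test_containment_and_boundary(self, small_insertions, small_annotation):
        gene_counts, site_table = tnseq.aggregate_footprints(
            small_insertions, small_annotation
        )
        gc = gene_counts.set_index("gene_id")
        # pos 150 (+7) and 180 (+3) inside geneA [100, 200]; 201 is outside
        assert gc.loc["geneA", "count_t0"] == 10
        assert gc.loc["geneB", "count_t0"] == 11
        assert gc.loc[tnseq.INTERGENIC, "count_t0"] == 5
        assert gc.loc["geneA", "n_sites"] == 2
        site_gene = site_table.set_index("pos")["gene_id"]
        assert site_gene[201] == tnseq.INTERGENIC

    def test_chromosome_mismatch_is_explicit(self, small_insertions, small_annotation):
        bad = small_insertions.assign(chrom="plasmid")
        with pytest.raises(ValueError, match="plasmid"):
            tnseq.aggregate_footprints(bad, small_annotation)

    def test_matches_brute_force_scan(self):
        """Totals equal a per-site containment scan over random intervals."""
        rng = np.random.default_rng(0)
        ins = pd.DataFrame(
            {
                "chrom": "c",
                "pos": rng.integers(1, 300, 10),
                "strand": "+",
                "sample": "t0",
                "count": rng.integers(0, 20, 10),
            }
        ).drop_duplicates(subset=["chrom", "pos", "strand", "sample"])
        starts = rng.integers(1, 250, 3)
        ann = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(3)],
                "chrom": "c",
                "start": starts,
                "end": starts + rng.integers(10, 80, 3),
                "strand": "+",
            }
        )
        gene_counts, _ = tnseq.aggregate_footprints(ins, ann)
        gc = gene_counts.set_index("gene_id")["count_t0"]
        for _, g in ann.iterrows():
            expected = ins.loc[
                (ins["pos"] >= g["start"]) & (ins["pos"] <= g["end"]), "count"
            ].sum()
            assert gc.get(g["gene_id"], 0) == expected

    def test_overlapping_genes_count_for_both(self):
        ins = pd.DataFrame(
            [{"chrom": "c", "pos": 50, "strand": "+", "sample": "t0", "count": 4}]
        )
        ann = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "chrom": "c",
                "start": [10, 40],
                "end": [60, 90],
                "strand": "+",
            }
        )
        gc, _ = tnseq.aggregate_footprints(ins, ann)
        assert (gc.set_index("gene_id")["count_t0"][["g1", "g2"]] == 4).all()


class TestNormalizeFpm:
    def test_proportions(self):
        gc = pd.DataFrame({"gene_id": ["A", "B"], "count_t0": [1, 3]})
        out = tnseq.normalize_fpm(gc)
        assert out["fpm_t0"].tolist() == [250000.0, 750000.0]

    def test_conservation(self):
        rng = np.random.default_rng(1)
        gc = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(50)], "count_t0": rng.poisson(40, 50)}
        )
        assert tnseq.normalize_fpm(gc)["fpm_t0"].sum() == pytest.approx(1e6, abs=1e-6)

    def test_all_zero_sample_named(self):
        gc = pd.DataFrame({"gene_id": ["A"], "count_t3": [0]})
        with pytest.raises(ValueError, match="t3"):
            tnseq.normalize_fpm(gc)


# ---------------------------------------------------------------------------
# exact rate-ratio test
# ---------------------------------------------------------------------------

def _enumerated_minlike_p(x1: int, n: int, pi: float) -> float:
    """Independent enumeration oracle using log-factorials directly."""
    k = np.arange(n + 1)
    logpmf = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(pi)
        + (n - k) * np.log1p(-pi)
    )
    pmf = np.exp(logpmf)
    return float(pmf[pmf <= pmf[x1] * (1 + 1e-10)].sum())


class TestRateRatioTest:
    def test_symmetric_mode_gives_one(self):
        assert tnseq.rate_ratio_test(6, 1e6, 6, 1e6) == 1.0

    def test_ten_vs_zero_equals_binomial_tail(self):
        # Binomial(10, 0.5) minimum-likelihood: only the two extreme outcomes
        p = tnseq.rate_ratio_test(10, 1e6, 0, 1e6)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_no_information_gives_one(self):
        assert tnseq.rate_ratio_test(0, 1e6, 0, 2e6) == 1.0

    @pytest.mark.parametrize("n1,n2", [(1e6, 1e6), (1e6, 3e6), (2e5, 7e5)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(3)
        pi = n1 / (n1 + n2)
        for _ in range(200):
            n = int(rng.integers(1, 201))
            x1 = int(rng.integers(0, n + 1))
            got = tnseq.rate_ratio_test(x1, n1, n - x1, n2)
            assert got == pytest.approx(_enumerated_minlike_p(x1, n, pi), abs=1e-12)

    def test_matches_scipy_binomtest(self):
        """Cross-check against an independent minlike implementation."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(1, 150))
            x1 = int(rng.integers(0, n + 1))
            got = tnseq.rate_ratio_test(x1, 2e6, n - x1, 1e6)
            ref = stats.binomtest(x1, n, 2 / 3).pvalue
            assert got == pytest.approx(ref, abs=1e-12)

    def test_doubled_tail_variant_bounds_minlike(self):
        p_min = tnseq.rate_ratio_test(14, 1e6, 4, 1e6, method="minlike")
        p_dbl = tnseq.rate_ratio_test(14, 1e6, 4, 1e6, method="doubled")
        assert 0 < p_min <= p_dbl <= 1

    @given(
        x1=st.integers(0, 120),
        x2=st.integers(0, 120),
        n1=st.integers(1, 10**7),
        n2=st.integers(1, 10**7),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_p_in_unit_interval(self, x1, x2, n1, n2):
        p = tnseq.rate_ratio_test(x1, n1, x2, n2)
        assert 0 < p <= 1


class TestAdjustPvalues:
    def test_bh_hand_stepup(self):
        q = tnseq.adjust_pvalues([0.01, 0.02, 0.03], method="BH")
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity_both_methods(self):
        for method in ("BH", "BY"):
            assert tnseq.adjust_pvalues([0.2], method=method) == pytest.approx([0.2])

    def test_all_ones(self):
        assert (tnseq.adjust_pvalues([1.0, 1.0, 1.0], method="BY") == 1.0).all()

    def test_nan_propagates(self):
        q = tnseq.adjust_pvalues([0.01, np.nan, 0.5], method="BH")
        assert np.isnan(q[1]) and not np.isnan(q[0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bh_no_larger_than_by(self, pvals):
        q_bh = tnseq.adjust_pvalues(pvals, method="BH")
        q_by = tnseq.adjust_pvalues(pvals, method="BY")
        assert (q_bh <= q_by + 1e-12).all()


# ---------------------------------------------------------------------------
# survival scores
# ---------------------------------------------------------------------------

class TestSurvivalScores:
    def _table(self, c_start, c_t0, c_t3):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(c_t0))],
                "count_start": c_start,
                "count_t0": c_t0,
                "count_t3": c_t3,
            }
        )

    def test_fourfold_change_scores_two(self):
        # equal totals, one gene 4x up, a large balancing background gene
        gst = tnseq.survival_scores(
            self._table([100, 1000], [100, 1000], [400, 700]), pseudocount=0
        )
        g = gst.set_index("gene_id")
        assert g.loc["g0", "survival_score"] == pytest.approx(2.0)

    def test_identity_scores_zero(self):
        gst = tnseq.survival_scores(self._table([50, 50], [50, 50], [50, 50]))
        assert gst["survival_score"].to_numpy() == pytest.approx(0.0)
        assert gst["start_score"].to_numpy() == pytest.approx(0.0)

    def test_zero_denominator_flagged_with_zero_pseudocount(self):
        gst = tnseq.survival_scores(
            self._table([10, 100], [0, 100], [50, 100]), pseudocount=0
        )
        g = gst.set_index("gene_id")
        assert np.isinf(g.loc["g0", "survival_score"])
        assert not g.loc["g0", "score_defined"]

    def test_enrichment_at_3h_is_positive(self):
        """Sign convention: more reads at 3 h than 0 h -> positive score."""
        gst = tnseq.survival_scores(self._table([5, 995], [5, 995], [120, 880]))
        g = gst.set_index("gene_id")
        assert g.loc["g0", "survival_score"] > 0
        assert g.loc["g0", "q_value"] <= g.loc["g0", "p_value"] or np.isclose(
            g.loc["g0", "q_value"], g.loc["g0", "p_value"]
        )

    def test_low_count_genes_not_tested(self):
        gst = tnseq.survival_scores(self._table([3, 900], [3, 900], [4, 900]))
        g = gst.set_index("gene_id")
        assert np.isnan(g.loc["g0", "p_value"])
        assert not np.isnan(g.loc["g1", "p_value"])

    def test_null_type_one_error_calibrated(self):
        """Poisson null with equal rates rejects at ~5%."""
        rng = np.random.default_rng(8)
        n = 2000
        lam = rng.uniform(200, 800, n)
        gst = tnseq.survival_scores(
            pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n)],
                    "count_t0": rng.poisson(lam),
                    "count_t3": rng.poisson(lam),
                }
            )
        )
        frac = (gst["p_value"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 3 * se


# ---------------------------------------------------------------------------
# high-confidence filter
# ---------------------------------------------------------------------------

class TestHighConfidenceFilter:
    def _sites(self, rows):
        return pd.DataFrame(
            [
                {
                    "gene_id": g,
                    "chrom": "c",
                    "pos": i + 1,
                    "strand": "+",
                    "count_t0": a,
                    "count_t3": b,
                }
                for i, (g, a, b) in enumerate(rows)
            ]
        )

    def test_two_concordant_extreme_sites_qualify(self):
        st_tbl = self._sites([("A", 5, 500), ("A", 5, 500), ("B", 100, 100)])
        flags = tnseq.high_confidence_filter(
            st_tbl, library_totals={"t0": 1e6, "t3": 1e6}
        )
        assert bool(flags["A"]) is True

    def test_discordant_sites_fail(self):
        st_tbl = self._sites([("A", 5, 500), ("A", 500, 5), ("B", 100, 100)])
        flags = tnseq.high_confidence_filter(
            st_tbl, library_totals={"t0": 1e6, "t3": 1e6}
        )
        assert bool(flags["A"]) is False

    def test_single_site_cannot_qualify(self):
        st_tbl = self._sites([("A", 5, 500), ("B", 100, 100)])
        flags = tnseq.high_confidence_filter(
            st_tbl, library_totals={"t0": 1e6, "t3": 1e6}
        )
        assert bool(flags["A"]) is False

    def test_matches_independent_per_site_recomputation(self, tnseq_sim):
        """Flags equal a from-scratch per-site test + BH + direction check."""
        site = tnseq_sim["site_table"]
        site = site[site["gene_id"] != tnseq.INTERGENIC]
        n0, n3 = site["count_t0"].sum(), site["count_t3"].sum()
        flags = tnseq.high_confidence_filter(
            site, library_totals={"t0": float(n0), "t3": float(n3)}
        )
        # oracle: direct scipy per-site tests
        pvals = []
        for x0, x3 in zip(site["count_t0"], site["count_t3"]):
            table = np.array([[x0, n0 - x0], [x3, n3 - x3]])
            exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if exp.min() < 5:
                pvals.append(stats.fisher_exact(table)[1])
            else:
                pvals.append(stats.chi2_contingency(table, correction=True)[1])
        from statsmodels.stats.multitest import multipletests

        q = multipletests(pvals, method="fdr_bh")[1]
        direction = np.sign(
            site["count_t3"].to_numpy() / n3 - site["count_t0"].to_numpy() / n0
        )
        expected = {}
        df = site.assign(q=q, direction=direction)
        for gene, g in df.groupby("gene_id"):
            sig = g[g["q"] < 0.1]
            dirs = set(sig["direction"]) - {0.0}
            expected[gene] = len(sig) >= 2 and len(dirs) == 1
        assert {g: bool(v) for g, v in flags.items()} == expected


# ---------------------------------------------------------------------------
# candidate lists
# ---------------------------------------------------------------------------

def _gst_from_rows(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "survival_score", "start_score", "q_value"]
    )


class TestCandidateLists:
    def test_concordant_start_sign_kept(self):
        gst = _gst_from_rows([("a", 2.0, 1.0, 0.001)])
        lists = tnseq.candidate_lists(gst)
        assert lists.positive == ["a"] and lists.negative == []

    def test_opposite_start_sign_discarded(self):
        gst = _gst_from_rows([("a", 2.0, -0.3, 0.001)])
        lists = tnseq.candidate_lists(gst)
        assert lists.positive == [] and lists.n_discarded_by_start == 1

    def test_missing_start_sample_instructs(self):
        gst = pd.DataFrame(
            {"gene_id": ["a"], "survival_score": [2.0], "q_value": [0.001]}
        )
        with pytest.raises(ValueError, match="use_start_filter=False"):
            tnseq.candidate_lists(gst)
        lists = tnseq.candidate_lists(gst, use_start_filter=False)
        assert lists.positive == ["a"]

    def test_matches_set_comprehension_oracle(self):
        rng = np.random.default_rng(5)
        gst = _gst_from_rows(
            [
                (f"g{i}", rng.normal(0, 1.2), rng.normal(0, 1.2), rng.uniform(0, 0.2))
                for i in range(100)
            ]
        )
        lists = tnseq.candidate_lists(gst, threshold=0.5, q_cut=0.05)
        pos = sorted(
            r.gene_id
            for r in gst.itertuples()
            if r.survival_score > 0.5
            and r.q_value < 0.05
            and np.sign(r.start_score) == np.sign(r.survival_score)
        )
        neg = sorted(
            r.gene_id
            for r in gst.itertuples()
            if r.survival_score < -0.5
            and r.q_value < 0.05
            and np.sign(r.start_score) == np.sign(r.survival_score)
        )
        assert lists.positive == pos and lists.negative == neg
        assert not (set(lists.positive) & set(lists.negative))

    def test_invariant_to_gene_order_and_sample_scaling(self, tnseq_sim):
        gst = tnseq_sim["gst"]
        base = tnseq.candidate_lists(gst)
        shuffled = tnseq.candidate_lists(
            gst.sample(frac=1, random_state=0).reset_index(drop=True)
        )
        assert base.positive == shuffled.positive
        assert base.negative == shuffled.negative
        # rescale all t3 counts by an integer factor: FPMs and scores identical
        scaled_counts = tnseq_sim["gene_counts"].copy()
        scaled_counts["count_t3"] = scaled_counts["count_t3"] * 3
        scaled = tnseq.candidate_lists(tnseq.survival_scores(scaled_counts))
        assert base.positive == scaled.positive
        assert base.negative == scaled.negative


class TestParameterRecovery:
    def test_known_effects_recovered(self, tnseq_sim):
        """Estimated scores regress on true effects with unit slope."""
        gst = tnseq_sim["gst"].set_index("gene_id")
        effects = tnseq_sim["effects"]
        truth = np.array(list(effects.values()))
        est = gst.loc[[f"g{g:04d}" for g in effects], "survival_score"].to_numpy()
        slope, intercept, r, _, _ = stats.linregress(truth, est)
        resid = est - (intercept + slope * truth)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert np.sqrt((resid**2).mean()) < 0.25
        assert r**2 > 0.98


def test_mean_insertion_spacing_arithmetic():
    assert tnseq.mean_insertion_spacing(4, 100) == 25.0
    with pytest.raises(ValueError):
        tnseq.mean_insertion_spacing(0)
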