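"""Gene-level survival profiling from transposon insertion counts.

A saturated transposon library is starved of thymidine; insertion sites are
sequenced before starvation ("Start", no outgrowth), at 0 h and at 3 h (both
with a short recovery outgrowth).  The abundance of reads at insertions in a
gene across time points measures how its disruption affects survival:

    survival score = log2( FPM_3h / FPM_0h )

where FPM is footprints (reads) per million, a library-size normalization.
A positive score means the disruption *helps* survival (cells carrying it
become relatively more abundant).  Significance comes from the exact
conditional rate-ratio test on raw counts, with step-up FDR control; the
"Start" sample filters out artifacts of differential regrowth during the
outgrowth, and a per-site test flags high-confidence genes supported by at
least two independently significant insertion sites agreeing in direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "aggregate_footprints",
    "normalize_fpm",
    "rate_ratio_test",
    "adjust_pvalues",
    "survival_scores",
    "high_confidence_filter",
    "candidate_lists",
    "mean_insertion_spacing",
    "CandidateLists",
    "MG1655_GENOME_LENGTH",
]

#: Length of the E. coli K-12 MG1655 reference chromosome (bp).
MG1655_GENOME_LENGTH = 4_641_652

INTERGENIC = "__intergenic__"


def mean_insertion_spacing(n_insertions: int, genome_length: int = MG1655_GENOME_LENGTH) -> float:
    """Mean distance in bp between insertion sites of a library.

    For a saturated library this is the genome length divided by the number
    of distinct insertion sites.
    """
    if n_insertions <= 0:
        raise ValueError("n_insertions must be positive")
    return genome_length / n_insertions


# ---------------------------------------------------------------------------
# Footprint aggregation
# ---------------------------------------------------------------------------

def aggregate_footprints(
    insertions: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign insertion sites to genes and sum read counts per gene and sample.

    Assignment is strand-agnostic containment in the 1-based inclusive gene
    interval; a site inside several overlapping genes counts toward all of
    them.  Sites inside no gene are collected under the ``__intergenic__``
    bucket.

    Parameters
    ----------
    insertions
        Site-level table with columns chrom, pos, strand, sample, count.
    annotation
        Gene table with columns gene_id, chrom, start, end, strand.

    Returns
    -------
    gene_counts : DataFrame
        One row per gene (plus the intergenic bucket), one ``count_<sample>``
        column per sample, and ``n_sites`` = number of distinct insertion
        sites with a positive count in any sample.
    site_table : DataFrame
        Per-site sub-table (gene_id, chrom, pos, strand and per-sample counts)
        for downstream per-site testing; intergenic sites included under the
        bucket id.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    ins_chroms = set(insertions["chrom"].unique())
    ann_chroms = set(annotation["chrom"].unique())
    unmatched = sorted(ins_chroms - ann_chroms)
    if unmatched:
        raise ValueError(
            f"insertion chromosome name(s) {unmatched} not present in annotation "
            f"(annotation has {sorted(ann_chroms)})"
        )

    # site -> genes containing it (possibly several; empty -> intergenic)
    sites = insertions[["chrom", "pos", "strand"]].drop_duplicates().reset_index(drop=True)
    assignments = []  # (chrom, pos, strand, gene_id)
    for chrom, chrom_sites in sites.groupby("chrom", sort=False):
        pos = chrom_sites["pos"].to_numpy()
        order = np.argsort(pos)
        sorted_pos = pos[order]
        covered = np.zeros(len(pos), dtype=bool)
        genes = annotation[annotation["chrom"] == chrom]
        for gene_id, start, end in zip(genes["gene_id"], genes["start"], genes["end"]):
            lo = np.searchsorted(sorted_pos, start, side="left")
            hi = np.searchsorted(sorted_pos, end, side="right")
            idx = order[lo:hi]
            covered[idx] = True
            for i in idx:
                assignments.append(
                    (chrom, pos[i], chrom_sites["strand"].iloc[i], gene_id)
                )
        for i in np.flatnonzero(~covered):
            assignments.append(
                (chrom, pos[i], chrom_sites["strand"].iloc[i], INTERGENIC)
            )
    assign_df = pd.DataFrame(
        assignments, columns=["chrom", "pos", "strand", "gene_id"]
    )

    wide = (
        insertions.pivot_table(
            index=["chrom", "pos", "strand"],
            columns="sample",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .rename(columns=lambda s: f"count_{s}")
        .reset_index()
    )
    site_table = assign_df.merge(wide, on=["chrom", "pos", "strand"], how="left")
    count_cols = [c for c in site_table.columns if c.startswith("count_")]

    gene_counts = site_table.groupby("gene_id", sort=True)[count_cols].sum().reset_index()
    n_sites = (
        site_table.assign(any_pos=site_table[count_cols].sum(axis=1) > 0)
        .groupby("gene_id")["any_pos"]
        .sum()
        .astype(int)
        .rename("n_sites")
    )
    gene_counts = gene_counts.merge(n_sites, on="gene_id")
    return gene_counts, site_table


def normalize_fpm(gene_counts: pd.DataFrame) -> pd.DataFrame:
    """Convert ``count_<sample>`` columns to ``fpm_<sample>`` (footprints per million).

    Each FPM column sums to 1e6 over the rows of the table.  Raises on an
    all-zero sample, naming it.
    """
    out = gene_counts.copy()
    for col in [c for c in gene_counts.columns if c.startswith("count_")]:
        sample = col[len("count_"):]
        total = gene_counts[col].sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has no reads; cannot normalize to FPM")
        out[f"fpm_{sample}"] = gene_counts[col] / total * 1e6
    return out


# ---------------------------------------------------------------------------
# Exact rate-ratio test
# ---------------------------------------------------------------------------

def rate_ratio_test(
    x1: int,
    n1: float,
    x2: int,
    n2: float,
    method: str = "minlike",
) -> float:
    """Two-sided exact test that two Poisson counts share a common rate.

    Conditional on the total ``x1 + x2``, the first count is Binomial with
    success probability ``n1 / (n1 + n2)`` under the null of rate ratio 1
    (``n1``/``n2`` are the library exposure totals).  The two-sided p-value
    sums the probabilities of all outcomes no more likely than the observed
    one (``method="minlike"``); ``method="doubled"`` doubles the smaller
    exact tail instead.

    Returns p in (0, 1]; ``x1 + x2 == 0`` carries no information and gives 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    if method not in ("minlike", "doubled"):
        raise ValueError(f"unknown method {method!r}")
    n = x1 + x2
    if n == 0:
        return 1.0
    pi = n1 / (n1 + n2)
    if method == "doubled":
        lower = stats.binom.cdf(x1, n, pi)
        upper = stats.binom.sf(x1 - 1, n, pi)
        return float(min(1.0, 2.0 * min(lower, upper)))
    # minimum-likelihood rule by full enumeration; the relative tolerance
    # guards against ties lost to floating point
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, pi)
    p_obs = pmf[x1]
    p = pmf[pmf <= p_obs * (1 + 1e-10)].sum()
    # guard against pmf underflow at extreme exposure ratios: p stays > 0
    return float(min(1.0, max(p, p_obs, np.finfo(float).tiny)))


def _rate_ratio_test_vec(x1, n1, x2, n2, method="minlike") -> np.ndarray:
    """Vector of :func:`rate_ratio_test` p-values (per-row enumeration)."""
    x1 = np.asarray(x1, dtype=np.int64)
    x2 = np.asarray(x2, dtype=np.int64)
    return np.array(
        [rate_ratio_test(int(a), n1, int(b), n2, method=method) for a, b in zip(x1, x2)]
    )


def adjust_pvalues(p, method: str = "BY") -> np.ndarray:
    """Step-up FDR-adjusted q-values (Benjamini-Hochberg or Benjamini-Yekutieli).

    NaN p-values propagate to NaN q-values; the remaining values are adjusted
    among themselves.
    """
    if method not in ("BH", "BY"):
        raise ValueError(f"method must be 'BH' or 'BY', got {method!r}")
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        sm_method = "fdr_bh" if method == "BH" else "fdr_by"
        q[mask] = multipletests(p[mask], method=sm_method)[1]
    return q


# ---------------------------------------------------------------------------
# Survival scores
# ---------------------------------------------------------------------------

def survival_scores(
    gene_counts: pd.DataFrame,
    pseudocount: float = 0.5,
    correction: str = "BY",
    min_total_reads: int = 10,
    library_totals: dict[str, float] | None = None,
    exclude_intergenic: bool = True,
    test_method: str = "minlike",
) -> pd.DataFrame:
    """Per-gene survival scores, exact-test p-values and q-values.

    ``survival_score = log2((fpm_t3 + eps) / (fpm_t0 + eps))`` with
    ``eps = pseudocount`` (in FPM units) applied to numerator and denominator;
    the exact rate-ratio test runs on the raw counts and library totals.  A
    ``start`` sample, when present, yields ``start_score`` (3 h vs Start) used
    by the outgrowth-artifact filter in :func:`candidate_lists`.

    Genes with fewer than ``min_total_reads`` reads across t0 + t3 are not
    tested (p and q are NaN).  With ``pseudocount=0`` a zero denominator
    yields an infinite score, flagged in ``score_defined`` and excluded from
    candidate lists downstream.
    """
    required = {"count_t0", "count_t3"}
    if not required <= set(gene_counts.columns):
        raise ValueError("gene_counts must have count_t0 and count_t3 columns")
    gc = gene_counts.copy()
    if exclude_intergenic:
        gc = gc[gc["gene_id"] != INTERGENIC].reset_index(drop=True)

    samples = [c[len("count_"):] for c in gc.columns if c.startswith("count_")]
    totals = {
        s: (library_totals[s] if library_totals else float(gc[f"count_{s}"].sum()))
        for s in samples
    }
    for s in samples:
        if totals[s] <= 0:
            raise ValueError(f"sample {s!r} has zero total reads")
        gc[f"fpm_{s}"] = gc[f"count_{s}"] / totals[s] * 1e6

    eps = float(pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log2((gc["fpm_t3"] + eps) / (gc["fpm_t0"] + eps))
    gc["survival_score"] = score
    gc["score_defined"] = np.isfinite(score)

    if "fpm_start" in gc.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            gc["start_score"] = np.log2((gc["fpm_t3"] + eps) / (gc["fpm_start"] + eps))

    testable = (gc["count_t0"] + gc["count_t3"]) >= min_total_reads
    p = np.full(len(gc), np.nan)
    p[testable.to_numpy()] = _rate_ratio_test_vec(
        gc.loc[testable, "count_t3"],
        totals["t3"],
        gc.loc[testable, "count_t0"],
        totals["t0"],
        method=test_method,
    )
    gc["p_value"] = p
    gc["q_value"] = adjust_pvalues(p, method=correction)
    return gc


# ---------------------------------------------------------------------------
# High-confidence per-site screening
# ---------------------------------------------------------------------------

def _site_proportion_test(x_t0, x_t3, n_t0, n_t3) -> float:
    """2x2 chi-squared with continuity correction for one site vs rest of library.

    Falls back to Fisher's exact test when any expected cell is below 5.
    """
    table = np.array(
        [[x_t0, n_t0 - x_t0], [x_t3, n_t3 - x_t3]], dtype=float
    )
    if table.min() < 0:
        raise ValueError("site count exceeds library total")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        return 1.0
    expected = row @ col / total
    if expected.min() < 5:
        return float(stats.fisher_exact(table.astype(np.int64))[1])
    return float(stats.chi2_contingency(table, correction=True)[1])


def high_confidence_filter(
    site_table: pd.DataFrame,
    site_q_cut: float = 0.1,
    library_totals: dict[str, float] | None = None,
    correction: str = "BH",
) -> pd.Series:
    """Flag genes supported by >=2 independently significant, concordant sites.

    Each insertion site is tested for a change in insertion frequency between
    t0 and t3 (site reads vs rest of library, two-proportion test); q-values
    are computed within the tested set.  A gene qualifies iff at least two of
    its sites reach ``q < site_q_cut`` *and* every significant site shifts in
    the same direction.  Genes with fewer than two sites cannot qualify.

    Returns a boolean Series indexed by gene_id.
    """
    st = site_table[site_table["gene_id"] != INTERGENIC].copy()
    for col in ("count_t0", "count_t3"):
        if col not in st.columns:
            raise ValueError(f"site_table must have a {col} column")
    n_t0 = library_totals["t0"] if library_totals else float(site_table["count_t0"].sum())
    n_t3 = library_totals["t3"] if library_totals else float(site_table["count_t3"].sum())

    p = np.array(
        [
            _site_proportion_test(x0, x3, n_t0, n_t3)
            for x0, x3 in zip(st["count_t0"], st["count_t3"])
        ]
    )
    st["site_p"] = p
    st["site_q"] = adjust_pvalues(p, method=correction)
    st["direction"] = np.sign(st["count_t3"] / n_t3 - st["count_t0"] / n_t0)

    def _gene_flag(g: pd.DataFrame) -> bool:
        sig = g[g["site_q"] < site_q_cut]
        if len(sig) < 2:
            return False
        dirs = set(sig["direction"]) - {0.0}
        return len(dirs) == 1

    return st.groupby("gene_id").apply(_gene_flag, include_groups=False).rename(
        "high_confidence"
    )


# ---------------------------------------------------------------------------
# Candidate lists
# ---------------------------------------------------------------------------

@dataclass
class CandidateLists:
    """Significant genes above the score threshold, split by sign.

    Members satisfy |survival_score| > threshold, q < q_cut, a defined score,
    and (unless the Start filter was explicitly disabled) a ``start_score``
    agreeing in sign with the survival score — the no-outgrowth control that
    discards artifacts of differential regrowth.
    """

    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)
    threshold: float = 0.5
    q_cut: float = 0.05
    n_above_threshold: int = 0
    n_discarded_by_start: int = 0


def candidate_lists(
    gst: pd.DataFrame,
    threshold: float = 0.5,
    q_cut: float = 0.05,
    use_start_filter: bool = True,
) -> CandidateLists:
    """Filter a gene survival table into positive and negative candidate lists."""
    if use_start_filter and "start_score" not in gst.columns:
        raise ValueError(
            "no 'start' sample in the survival table; pass use_start_filter=False "
            "to run explicitly without the no-outgrowth control"
        )
    df = gst.copy()
    finite = np.isfinite(df["survival_score"]) & ~df["q_value"].isna()
    sig = finite & (df["q_value"] < q_cut) & (df["survival_score"].abs() > threshold)
    above = df[sig]
    n_above = len(above)
    if use_start_filter:
        keep = np.sign(above["survival_score"]) == np.sign(above["start_score"])
        discarded = int((~keep).sum())
        above = above[keep]
    else:
        discarded = 0
    pos = above.loc[above["survival_score"] > 0, "gene_id"].tolist()
    neg = above.loc[above["survival_score"] < 0, "gene_id"].tolist()
    return CandidateLists(
        positive=sorted(pos),
        negative=sorted(neg),
        threshold=threshold,
        q_cut=q_cut,
        n_above_threshold=n_above,
        n_discarded_by_start=discarded,
    )
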