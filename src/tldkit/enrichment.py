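"""Stress-gene-set enrichment of screen hits against a fitness compendium.

Genome-wide fitness compendia (e.g. the Fitness Browser) report, per gene and
stress condition, a signed fitness score and a t-like statistic.  Genes are
partitioned into *beneficial* (needed for fitness under the stress: fitness
and t both strongly negative), *deleterious* (both strongly positive) and
*neutral*.  Deleterious genes are dropped, the beneficial set defines the
condition-relevant gene set, and the neutral set the background; enrichment
of a hit list in the beneficial set is measured as a log2 fold enrichment of
proportions with a 2x2 chi-squared test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetPartition",
    "EnrichmentResult",
    "partition_fitness",
    "enrichment_test",
    "two_by_two_test",
]


@dataclass
class GeneSetPartition:
    beneficial: set = field(default_factory=set)
    deleterious: set = field(default_factory=set)
    neutral: set = field(default_factory=set)
    beneficial_cut: tuple[float, float] = (-1.0, -2.0)
    deleterious_cut: tuple[float, float] = (1.0, 2.0)

    @property
    def universe(self) -> set:
        """Background for enrichment: beneficial plus neutral genes."""
        return self.beneficial | self.neutral


@dataclass
class EnrichmentResult:
    log2_fold_enrichment: float
    chi2_statistic: float
    p_value: float
    table: np.ndarray  # [[hit&set, hit&bg], [nonhit&set, nonhit&bg]]
    odds_ratio: float


def partition_fitness(
    records: pd.DataFrame,
    beneficial_cut: tuple[float, float] = (-1.0, -2.0),
    deleterious_cut: tuple[float, float] = (1.0, 2.0),
) -> GeneSetPartition:
    """Partition a per-gene fitness table into beneficial/deleterious/neutral sets.

    ``beneficial_cut = (f, t)`` requires fitness < f AND t_score < t;
    ``deleterious_cut = (f, t)`` requires fitness > f AND t_score > t (both
    cuts must be met — a strong fitness score with a weak t statistic stays
    neutral).  Per-condition overrides simply pass different cuts.
    """
    fb, tb = beneficial_cut
    fd, td = deleterious_cut
    if fb >= 0 or tb >= 0 or fd <= 0 or td <= 0:
        raise ValueError("beneficial cuts must be negative and deleterious cuts positive")
    beneficial = (records["fitness"] < fb) & (records["t_score"] < tb)
    deleterious = (records["fitness"] > fd) & (records["t_score"] > td)
    genes = records["gene_id"]
    return GeneSetPartition(
        beneficial=set(genes[beneficial]),
        deleterious=set(genes[deleterious & ~beneficial]),
        neutral=set(genes[~beneficial & ~deleterious]),
        beneficial_cut=beneficial_cut,
        deleterious_cut=deleterious_cut,
    )


def two_by_two_test(
    table: np.ndarray, correction: bool = False, fisher_fallback: bool = True
) -> tuple[float, float]:
    """Chi-squared statistic and p for a 2x2 table, Fisher exact on degenerate margins."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if fisher_fallback and (
        (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    ):
        return np.nan, float(stats.fisher_exact(table.astype(np.int64))[1])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def enrichment_test(
    hits,
    partition: GeneSetPartition,
    ratio: str = "proportion",
    correction: bool = False,
) -> EnrichmentResult:
    """Enrichment of a hit list in the beneficial set of a partition.

    The universe is beneficial + neutral (deleterious genes are excluded
    beforehand); hits outside the universe are dropped with a warning.

        log2FE = log2[ (|hits ∩ beneficial| / |hits|) / (|beneficial| / |universe|) ]

    ``ratio="odds"`` reports the log2 odds ratio of the 2x2 table instead.
    The chi-squared test runs without continuity correction by default.
    """
    hits = set(hits)
    universe = partition.universe
    outside = hits - universe
    if outside:
        warnings.warn(
            f"{len(outside)} hit(s) not in the partition universe were dropped",
            stacklevel=2,
        )
        hits &= universe
    beneficial = partition.beneficial
    if not hits:
        raise ValueError("no hits inside the partition universe")
    if not beneficial:
        raise ValueError("partition has an empty beneficial set")

    a = len(hits & beneficial)
    b = len(hits) - a
    c = len(beneficial) - a
    d = len(universe) - len(hits) - c
    table = np.array([[a, b], [c, d]], dtype=float)

    prop_hits = a / len(hits)
    prevalence = len(beneficial) / len(universe)
    with np.errstate(divide="ignore"):
        if ratio == "proportion":
            log2fe = float(np.log2(prop_hits / prevalence)) if prop_hits > 0 else -np.inf
        elif ratio == "odds":
            log2fe = float(np.log2((a * d) / (b * c))) if min(a, b, c, d) > 0 else np.nan
        else:
            raise ValueError(f"unknown ratio {ratio!r}")
    chi2, p = two_by_two_test(table, correction=correction)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return EnrichmentResult(
        log2_fold_enrichment=log2fe,
        chi2_statistic=chi2,
        p_value=p,
        table=table,
        odds_ratio=float(odds),
    )
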