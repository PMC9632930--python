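"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator is a pure function of its parameters and seed (bit-identical
reruns) and returns the data in the same shape the corresponding reader
produces, alongside a truth record consumed by the recovery test harnesses.
The simulators emulate the *statistical* structure the analyses assume —
multinomial sequencing of a skewed insertion library under selection and
outgrowth, scatter-confounded log-normal fluorescence with crossed batch and
replicate effects, negative-binomial expression and colony counts — not the
underlying biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TnseqTruth",
    "sim_tnseq",
    "FlowTruth",
    "sim_flow",
    "sim_expression",
    "sim_sort",
]


# ---------------------------------------------------------------------------
# Tn-seq
# ---------------------------------------------------------------------------

@dataclass
class TnseqTruth:
    """Design of a simulated transposon survival-profiling experiment.

    ``effects`` maps gene index -> true survival effect S_g, the log2 change
    in relative abundance of insertions in that gene over 3 h of starvation
    (unlisted genes are neutral).  ``outgrowth_fitness`` maps gene index ->
    per-doubling growth-rate factor during the recovery outgrowth (captured
    identically by the t0 and t3 outgrowths, hence cancelled by the survival
    score but visible against the "Start" sample).  Sequencing depth applies
    per sample.  ``dead_cell_fraction`` is the share of pre-selection DNA
    that persists from dead cells at 3 h; the outgrowth amplifies live signal
    by 2**outgrowth_doublings over it.
    """

    n_genes: int = 2000
    mean_sites_per_gene: float = 10.0
    gene_length: int = 900
    intergenic_gap: int = 100
    depth: float = 1e7
    effects: dict[int, float] = field(default_factory=dict)
    outgrowth_fitness: dict[int, float] = field(default_factory=dict)
    outgrowth_doublings: float = 2.5
    dead_cell_fraction: float = 0.05
    chrom: str = "chr"

    def gene_interval(self, g: int) -> tuple[int, int]:
        span = self.gene_length + self.intergenic_gap
        start = g * span + 1
        return start, start + self.gene_length - 1

    def annotation(self) -> pd.DataFrame:
        rows = []
        for g in range(self.n_genes):
            start, end = self.gene_interval(g)
            rows.append(
                {
                    "gene_id": f"g{g:04d}",
                    "chrom": self.chrom,
                    "start": start,
                    "end": end,
                    "strand": "+",
                }
            )
        return pd.DataFrame(rows)


def sim_tnseq(truth: TnseqTruth, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an insertion table for the Start / t0 / t3 design.

    Per-site library abundances are Exponential (a skewed library); the
    "Start" sample is a multinomial draw from them.  t0 applies each gene's
    outgrowth fitness over ``outgrowth_doublings`` doublings; t3 additionally
    applies the survival effect 2**S_g and mixes in the residual dead-cell
    signal with weight dead_cell_fraction / (dead_cell_fraction +
    2**outgrowth_doublings) — dead DNA is not amplified during the outgrowth.

    Returns (insertion table, annotation).
    """
    rng = np.random.default_rng(seed)
    n_sites_per_gene = np.maximum(
        rng.poisson(truth.mean_sites_per_gene, truth.n_genes), 1
    )
    gene_of_site = np.repeat(np.arange(truth.n_genes), n_sites_per_gene)
    positions = np.concatenate(
        [
            truth.gene_interval(g)[0]
            + rng.choice(truth.gene_length, size=k, replace=False)
            for g, k in enumerate(n_sites_per_gene)
        ]
    )
    strands = rng.choice(["+", "-"], size=len(positions))

    abundance = rng.exponential(1.0, size=len(positions))
    s_g = np.zeros(truth.n_genes)
    for g, s in truth.effects.items():
        s_g[g] = s
    f_g = np.ones(truth.n_genes)
    for g, f in truth.outgrowth_fitness.items():
        f_g[g] = f

    outgrowth = f_g[gene_of_site] ** truth.outgrowth_doublings
    start_rel = abundance / abundance.sum()
    t0_rel = abundance * outgrowth
    t0_rel = t0_rel / t0_rel.sum()
    live = abundance * (2.0 ** s_g[gene_of_site]) * outgrowth
    live = live / live.sum()
    w = truth.dead_cell_fraction / (
        truth.dead_cell_fraction + 2.0**truth.outgrowth_doublings
    )
    t3_rel = (1 - w) * live + w * start_rel

    depth = int(truth.depth)
    frames = []
    for sample, rel in (("start", start_rel), ("t0", t0_rel), ("t3", t3_rel)):
        counts = rng.multinomial(depth, rel)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": truth.chrom,
                    "pos": positions,
                    "strand": strands,
                    "sample": sample,
                    "count": counts,
                }
            )
        )
    insertions = pd.concat(frames, ignore_index=True)
    return insertions, truth.annotation()


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

@dataclass
class FlowTruth:
    """Design of a simulated flow-cytometry acquisition.

    ``strains`` maps condition name -> true strain effect c (log2
    fluorescence units).  Events are generated per strain x batch x rep cell:
    log2 scatter values are Normal (per-strain means allow size-confounded
    designs via ``strain_fsc_shift``), the dye signal is
    2**(a*log2 fsc + b*log2 ssc + c + batch + rep + noise), and the measured
    fluorescence adds a smooth scatter-dependent autofluorescence surface.
    Matched no-dye events carry autofluorescence only.
    """

    strains: dict[str, float] = field(default_factory=lambda: {"ref": 0.0, "alt": 0.0})
    a: float = 0.8
    b: float = 0.3
    batch_sd: float = 0.2
    rep_sd: float = 0.1
    noise_sd: float = 0.5
    n_batches: int = 3
    n_reps: int = 4
    events_per_cell: int = 400
    nodye_events_per_batch: int = 1500
    log2_fsc_mean: float = 10.0
    log2_fsc_sd: float = 0.6
    log2_ssc_mean: float = 9.5
    log2_ssc_sd: float = 0.6
    strain_fsc_shift: dict[str, float] = field(default_factory=dict)
    signal_scale: float = 200.0       # linear gain applied to the dye term
    auto_base: float = 60.0
    auto_fsc_coef: float = 0.015
    auto_ssc_coef: float = 0.008
    auto_noise_sd: float = 8.0


def _autofluor(truth: FlowTruth, fsc: np.ndarray, ssc: np.ndarray) -> np.ndarray:
    return truth.auto_base + truth.auto_fsc_coef * fsc + truth.auto_ssc_coef * ssc


def sim_flow(truth: FlowTruth, seed: int = 0) -> pd.DataFrame:
    """Simulate a gated event table (dyed strains plus no-dye controls)."""
    rng = np.random.default_rng(seed)
    batches = [f"b{i}" for i in range(truth.n_batches)]
    reps = [f"r{i}" for i in range(truth.n_reps)]
    batch_eff = dict(zip(batches, rng.normal(0, truth.batch_sd, truth.n_batches)))
    rep_eff = dict(zip(reps, rng.normal(0, truth.rep_sd, truth.n_reps)))

    frames = []
    for strain, c in truth.strains.items():
        shift = truth.strain_fsc_shift.get(strain, 0.0)
        for batch in batches:
            for rep in reps:
                n = truth.events_per_cell
                lfsc = rng.normal(truth.log2_fsc_mean + shift, truth.log2_fsc_sd, n)
                lssc = rng.normal(truth.log2_ssc_mean + shift, truth.log2_ssc_sd, n)
                fsc, ssc = 2.0**lfsc, 2.0**lssc
                signal = truth.signal_scale * 2.0 ** (
                    truth.a * lfsc
                    + truth.b * lssc
                    + c
                    + batch_eff[batch]
                    + rep_eff[rep]
                    + rng.normal(0, truth.noise_sd, n)
                    - truth.a * truth.log2_fsc_mean
                    - truth.b * truth.log2_ssc_mean
                )
                fluor = (
                    _autofluor(truth, fsc, ssc)
                    + rng.normal(0, truth.auto_noise_sd, n)
                    + signal
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "fsc": fsc,
                            "ssc": ssc,
                            "fluor": fluor,
                            "strain_condition": strain,
                            "batch": batch,
                            "rep": rep,
                            "is_nodye": False,
                        }
                    )
                )
    for batch in batches:
        n = truth.nodye_events_per_batch
        lfsc = rng.normal(truth.log2_fsc_mean, truth.log2_fsc_sd, n)
        lssc = rng.normal(truth.log2_ssc_mean, truth.log2_ssc_sd, n)
        fsc, ssc = 2.0**lfsc, 2.0**lssc
        fluor = _autofluor(truth, fsc, ssc) + rng.normal(0, truth.auto_noise_sd, n)
        frames.append(
            pd.DataFrame(
                {
                    "fsc": fsc,
                    "ssc": ssc,
                    "fluor": fluor,
                    "strain_condition": "nodye",
                    "batch": batch,
                    "rep": "r0",
                    "is_nodye": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def sim_expression(
    n_genes: int,
    lfc_truth: dict[int, float] | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
    n_reps: int = 2,
    mean_log10_expr: float = 2.0,
    sd_log10_expr: float = 0.8,
    conditions: tuple[str, str] = ("evolved", "parental"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an NB count matrix with known per-gene log2 fold changes.

    The second condition carries the baseline means; the first is shifted by
    2**LFC for genes listed in ``lfc_truth``.  Gene lengths are log-normal.
    Returns (count matrix in reader layout, truth LFC Series by gene_id).
    """
    rng = np.random.default_rng(seed)
    lfc_truth = lfc_truth or {}
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    lengths = np.maximum(rng.lognormal(np.log(1000), 0.4, n_genes), 100).astype(int)
    base_mean = 10 ** rng.normal(mean_log10_expr, sd_log10_expr, n_genes)
    lfc = np.zeros(n_genes)
    for g, v in lfc_truth.items():
        lfc[g] = v

    def _nb(mean: np.ndarray) -> np.ndarray:
        if dispersion <= 0:
            return rng.poisson(mean)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mean))

    # counts scale with gene length so that per-kb rates recover the truth
    out = {"gene_id": gene_ids, "length_bp": lengths}
    kb = lengths / 1e3
    cond_a, cond_b = conditions
    for r_i in range(n_reps):
        out[f"{cond_a}_{r_i + 1}"] = _nb(base_mean * kb * 2.0**lfc)
        out[f"{cond_b}_{r_i + 1}"] = _nb(base_mean * kb)
    counts = pd.DataFrame(out)
    truth = pd.Series(lfc, index=gene_ids, name="lfc_truth")
    return counts, truth


# ---------------------------------------------------------------------------
# Sort survival
# ---------------------------------------------------------------------------

def sim_sort(
    rates: dict[tuple[str, str], float],
    dispersion: float = 0.05,
    n_sorted: int = 1000,
    replicates_per_dye: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate sorted-fraction colony counts.

    ``rates`` maps (dye, level) -> per-cell survival rate.  Replicates per
    dye default to the study design (BCECF 5, pHrodo 7, nodye 4); replicate
    i of every dye shares experiment date ``d{i}`` (parallel experiments), so
    date effects are identified across dyes.  Counts are NB around
    rate * n_sorted, truncated to [0, n_sorted].
    """
    rng = np.random.default_rng(seed)
    replicates_per_dye = replicates_per_dye or {"BCECF": 5, "pHrodo": 7, "nodye": 4}
    dyes = sorted({d for d, _ in rates})
    rows = []
    for dye in dyes:
        n_rep = replicates_per_dye.get(dye, 5)
        for r_i in range(n_rep):
            date = f"d{r_i}"
            for level in ("low", "high"):
                if (dye, level) not in rates:
                    raise ValueError(f"no rate given for ({dye!r}, {level!r})")
                mu = rates[(dye, level)] * n_sorted
                if dispersion <= 0:
                    k = rng.poisson(mu)
                else:
                    r = 1.0 / dispersion
                    k = rng.negative_binomial(r, r / (r + mu))
                rows.append(
                    {
                        "survivors": int(min(k, n_sorted)),
                        "n_sorted": n_sorted,
                        "dye": dye,
                        "level": level,
                        "date": date,
                    }
                )
    return pd.DataFrame(rows)
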