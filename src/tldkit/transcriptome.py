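"""RNA-seq normalization and genetic-transcriptional concordance.

Expression is normalized to RPKM and TPM from gene-level counts and lengths.
Between-condition log2 fold changes of TPM are joined to the Tn-seq survival
table to find *concordant* genes: a gene whose disruption helps survival
(positive survival score) and whose expression drops in the TLD-resistant
strain ("exacerbates" killing when intact), or the mirror image
("alleviates").  Differential-expression q-values from an external
negative-binomial test can be consumed but are not computed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import two_by_two_test

__all__ = [
    "compute_rpkm_tpm",
    "expression_lfc",
    "concordance_candidates",
    "concordance_enrichment",
]


def compute_rpkm_tpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Add ``rpkm_<sample>`` and ``tpm_<sample>`` columns to a count matrix.

    ``counts`` has gene_id, length_bp and one raw-count column per sample.
    RPKM = count / (length in kb x total reads in millions); TPM rescales the
    per-kb rate so each sample sums to 1e6.
    """
    if (counts["length_bp"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    out = counts.copy()
    length_kb = counts["length_bp"] / 1e3
    samples = [c for c in counts.columns if c not in ("gene_id", "length_bp")]
    for s in samples:
        total = counts[s].sum()
        if total <= 0:
            raise ValueError(f"sample {s!r} has zero total counts")
        out[f"rpkm_{s}"] = counts[s] / length_kb / (total / 1e6)
        rate = counts[s] / length_kb
        out[f"tpm_{s}"] = rate / rate.sum() * 1e6
    return out


def expression_lfc(tpm_a, tpm_b, pseudocount: float = 1.0) -> np.ndarray:
    """log2((tpm_a + eps) / (tpm_b + eps)); first argument is the numerator condition.

    Convention: pass the evolved/starved condition first, so a positive LFC
    means up-regulation in the resistant or stressed state.
    """
    a = np.asarray(tpm_a, dtype=float)
    b = np.asarray(tpm_b, dtype=float)
    eps = float(pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2((a + eps) / (b + eps))


def _join_scores_lfc(
    gst: pd.DataFrame, lfc: pd.Series, min_tpm: float | None, tpm: pd.DataFrame | None
) -> pd.DataFrame:
    df = gst[["gene_id", "survival_score", "q_value"]].merge(
        lfc.rename("lfc"), left_on="gene_id", right_index=True, how="inner"
    )
    if df.empty:
        raise ValueError("gene universes of the survival table and LFC vector do not overlap")
    if min_tpm is not None and tpm is not None:
        tpm_cols = [c for c in tpm.columns if c.startswith("tpm_")]
        expressed = tpm.loc[(tpm[tpm_cols] >= min_tpm).any(axis=1), "gene_id"]
        df = df[df["gene_id"].isin(set(expressed))]
    return df


def concordance_candidates(
    gst: pd.DataFrame,
    lfc: pd.Series,
    score_cut: float = 0.5,
    lfc_cut: float = 0.5,
    q_cut: float = 0.05,
    comparison: str = "",
    tpm: pd.DataFrame | None = None,
    min_tpm: float | None = 5.0,
    de_q: pd.Series | None = None,
    de_q_cut: float | None = None,
) -> pd.DataFrame:
    """Genes whose knockout fitness and expression change point the same way.

    exacerbates: survival_score > +score_cut (disruption helps, so the intact
    gene exacerbates killing) and lfc < -lfc_cut (down-regulated in the
    resistant strain).  alleviates: survival_score < -score_cut and
    lfc > +lfc_cut.  Survival significance q < q_cut is required; genes below
    ``min_tpm`` TPM in every sample of ``tpm`` are excluded (stringent
    low-count filter), and an external DE q-value cut is applied when both
    ``de_q`` and ``de_q_cut`` are given.
    """
    df = _join_scores_lfc(gst, lfc, min_tpm, tpm)
    df = df[np.isfinite(df["survival_score"]) & (df["q_value"] < q_cut)]
    if de_q is not None and de_q_cut is not None:
        df = df.merge(de_q.rename("de_q"), left_on="gene_id", right_index=True, how="left")
        df = df[df["de_q"] < de_q_cut]
    exa = (df["survival_score"] > score_cut) & (df["lfc"] < -lfc_cut)
    alle = (df["survival_score"] < -score_cut) & (df["lfc"] > lfc_cut)
    out = df[exa | alle].copy()
    out["direction"] = np.where(out["survival_score"] > 0, "exacerbates", "alleviates")
    out["comparison"] = comparison
    return out[["gene_id", "survival_score", "lfc", "direction", "comparison"]].reset_index(
        drop=True
    )


def concordance_enrichment(
    gst: pd.DataFrame,
    lfc: pd.Series,
    score_cut: float = 0.5,
    lfc_cut: float = 0.5,
    q_cut: float = 0.05,
    de_q: pd.Series | None = None,
    de_q_cut: float | None = None,
) -> dict:
    """2x2 enrichment of (KO-harmful AND up-regulated) genes over the joined universe.

    KO-harmful: significant survival score < -score_cut (the gene's product
    protects against killing).  Up-regulated: lfc > +lfc_cut (optionally also
    requiring an external DE q-value).  Returns log2 fold enrichment of the
    overlap over independence, the chi-squared statistic and p (Fisher exact
    on degenerate margins), and the table.
    """
    df = _join_scores_lfc(gst, lfc, None, None)
    harmful = (
        np.isfinite(df["survival_score"])
        & (df["q_value"] < q_cut)
        & (df["survival_score"] < -score_cut)
    ).to_numpy()
    up = (df["lfc"] > lfc_cut).to_numpy()
    if de_q is not None and de_q_cut is not None:
        dq = df["gene_id"].map(de_q).to_numpy(dtype=float)
        up &= dq < de_q_cut
    a = int((harmful & up).sum())
    b = int((harmful & ~up).sum())
    c = int((~harmful & up).sum())
    d = int((~harmful & ~up).sum())
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p = two_by_two_test(table, correction=False)
    n = len(df)
    expected = (a + b) * (a + c) / n if n else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fe = float(np.log2(a / expected)) if expected > 0 and a > 0 else -np.inf
    return {
        "log2_fold_enrichment": log2fe,
        "chi2_statistic": chi2,
        "p_value": p,
        "table": table,
        "n_genes": n,
    }
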