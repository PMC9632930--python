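"""Size-corrected flow-cytometry fluorescence modeling.

Per-cell dye fluorescence confounds the biological signal with cell size and
shape (proxied by forward and side scatter, FSC/SSC) and with dye-independent
autofluorescence.  The correction pipeline is:

1. gate out noise events (log2(fsc) and log2(ssc) must exceed 8);
2. fit a locally weighted (LOESS) surface predicting fluorescence from
   (FSC, SSC) on the pooled no-dye events of each acquisition batch, and
   subtract its prediction from every event (``fluor_adj``);
3. fit a linear mixed model on the log2 adjusted signal,

       log2(fluor_adj) ~ a*log2(fsc) + b*log2(ssc) + c_strain
                         + (1 | batch) + (1 | rep),

   with crossed random intercepts for acquisition day and biological
   replicate.  ``c_strain`` — the per-strain/condition mean fluorescence
   after removing size-explained variation — is the quantity of biological
   interest, reported relative to a designated reference condition;
4. Wald contrasts between conditions test for fluorescence (e.g.
   acidification) differences.

A per-cell ``log_fluor_corrected = log2(fluor_adj) - a*log2(fsc) -
b*log2(ssc)`` is provided for plotting and sorting thresholds only; it is
never re-fed to the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gate_events",
    "Loess2D",
    "AutofluorescenceModel",
    "fit_autofluorescence",
    "subtract_autofluorescence",
    "SizeModelFit",
    "fit_size_model",
    "corrected_fluorescence",
    "contrast_strains",
    "significance_stars",
]


def gate_events(events: pd.DataFrame, min_log2: float = 8.0) -> pd.DataFrame:
    """Keep events with log2(fsc) > min_log2 AND log2(ssc) > min_log2 (strict).

    The fraction removed is recorded in ``.attrs['fraction_removed']``.
    Raises if nothing survives the gate.
    """
    fsc = events["fsc"].to_numpy(dtype=float)
    ssc = events["ssc"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        keep = (np.log2(fsc, where=fsc > 0, out=np.full(len(events), -np.inf)) > min_log2) & (
            np.log2(ssc, where=ssc > 0, out=np.full(len(events), -np.inf)) > min_log2
        )
    if not keep.any():
        raise ValueError("gating removed all events")
    out = events[keep].reset_index(drop=True)
    out.attrs["fraction_removed"] = 1.0 - keep.mean()
    return out


# ---------------------------------------------------------------------------
# 2-D LOESS
# ---------------------------------------------------------------------------

class Loess2D:
    """Locally weighted degree-1 regression surface over two predictors.

    For each query point the nearest ``span`` fraction of training points
    (Euclidean distance after per-dimension scaling) is fit with a tricube-
    weighted linear model.  Query points outside the training bounding box
    are clamped to it (nearest-boundary prediction) and flagged as
    extrapolated.
    """

    def __init__(self, span: float = 0.5, max_train: int = 4000):
        if not 0 < span <= 1:
            raise ValueError("span must be in (0, 1]")
        self.span = span
        self.max_train = max_train

    def fit(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 2 or x.shape[1] != 2 or len(x) != len(y):
            raise ValueError("x must be (n, 2) with matching y")
        # canonical ordering makes the fit invariant to input row order
        order = np.lexsort((y, x[:, 1], x[:, 0]))
        x, y = x[order], y[order]
        if len(x) > self.max_train:
            rng = rng or np.random.default_rng(0)
            idx = rng.choice(len(x), self.max_train, replace=False)
            x, y = x[idx], y[idx]
        self._x = x
        self._y = y
        self._lo = x.min(axis=0)
        self._hi = x.max(axis=0)
        scale = x.std(axis=0)
        self._scale = np.where(scale > 0, scale, 1.0)
        self._k = max(4, int(np.ceil(self.span * len(x))))
        return self

    def predict(self, x: np.ndarray, return_flags: bool = False):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        extrapolated = ((x < self._lo) | (x > self._hi)).any(axis=1)
        xq = np.clip(x, self._lo, self._hi)
        xt = self._x / self._scale
        yhat = np.empty(len(xq))
        for i, q in enumerate(xq / self._scale):
            d = np.sqrt(((xt - q) ** 2).sum(axis=1))
            if self._k < len(d):
                nn = np.argpartition(d, self._k - 1)[: self._k]
            else:
                nn = np.arange(len(d))
            dn = d[nn]
            dmax = dn.max()
            if dmax == 0:
                yhat[i] = self._y[nn].mean()
                continue
            w = (1 - (dn / dmax) ** 3) ** 3
            w = np.maximum(w, 1e-12)
            X = np.column_stack([np.ones(len(nn)), xt[nn] - q])
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], self._y[nn] * sw, rcond=None)
            yhat[i] = beta[0]
        if return_flags:
            return yhat, extrapolated
        return yhat


@dataclass
class AutofluorescenceModel:
    """Per-batch LOESS surfaces predicting fluorescence from (fsc, ssc).

    Fits are trained on gated no-dye events pooled across strains within each
    acquisition batch; predictors are the raw scatter intensities.
    """

    span: float
    surfaces: dict = field(default_factory=dict)  # batch -> Loess2D

    def predict(self, batch: str, fsc, ssc, return_flags: bool = False):
        if batch not in self.surfaces:
            raise KeyError(f"no autofluorescence model trained for batch {batch!r}")
        x = np.column_stack([np.asarray(fsc, dtype=float), np.asarray(ssc, dtype=float)])
        return self.surfaces[batch].predict(x, return_flags=return_flags)


def fit_autofluorescence(
    nodye_events: pd.DataFrame,
    span: float = 0.5,
    min_events: int = 500,
    seed: int = 0,
) -> AutofluorescenceModel:
    """Fit the autofluorescence surface per analysis batch from no-dye events."""
    model = AutofluorescenceModel(span=span)
    rng = np.random.default_rng(seed)
    for batch, g in nodye_events.groupby("batch", sort=True):
        if len(g) < min_events:
            raise ValueError(
                f"batch {batch!r} has only {len(g)} no-dye events "
                f"(need >= {min_events})"
            )
        x = np.column_stack(
            [g["fsc"].to_numpy(dtype=float), g["ssc"].to_numpy(dtype=float)]
        )
        model.surfaces[batch] = Loess2D(span=span).fit(
            x, g["fluor"].to_numpy(dtype=float), rng=rng
        )
    return model


def subtract_autofluorescence(
    events: pd.DataFrame, model: AutofluorescenceModel
) -> pd.DataFrame:
    """Subtract the batch-matched LOESS autofluorescence prediction per event.

    Adds ``fluor_adj`` and an ``extrapolated`` flag for events outside the
    training scatter range (those receive the nearest-boundary prediction).
    """
    out = events.copy()
    out["fluor_adj"] = np.nan
    out["extrapolated"] = False
    for batch, g in out.groupby("batch", sort=False):
        pred, flags = model.predict(batch, g["fsc"], g["ssc"], return_flags=True)
        out.loc[g.index, "fluor_adj"] = g["fluor"].to_numpy(dtype=float) - pred
        out.loc[g.index, "extrapolated"] = flags
    return out


# ---------------------------------------------------------------------------
# Mixed-effects size model
# ---------------------------------------------------------------------------

@dataclass
class SizeModelFit:
    a: float                      # fixed-effect slope on log2(fsc)
    b: float                      # fixed-effect slope on log2(ssc)
    c: pd.Series                  # per-condition effects, reference at exactly 0
    c_conf_int: pd.DataFrame      # 95% Wald intervals for c (columns lower/upper)
    a_conf_int: tuple[float, float]
    b_conf_int: tuple[float, float]
    reference: str
    batch_var: float
    rep_var: float
    resid_var: float
    excluded_fraction: pd.Series  # per condition, share of fluor_adj <= 0 dropped
    params: pd.Series             # raw fixed-effect vector (internal naming)
    cov_params: pd.DataFrame
    converged: bool

    def c_param_name(self, condition: str) -> str | None:
        """Internal fixed-effect name for a condition (None for the reference)."""
        if condition == self.reference:
            return None
        name = f"C(strain_condition, Treatment(reference='{self.reference}'))[T.{condition}]"
        if name not in self.params.index:
            raise KeyError(f"condition {condition!r} not in fit")
        return name


def fit_size_model(
    events: pd.DataFrame,
    reference: str | None = None,
    offset_mode: str = "drop",
) -> SizeModelFit:
    """Fit the crossed-random-effects size model on log2 adjusted fluorescence.

    ``events`` needs fluor_adj (from :func:`subtract_autofluorescence`), fsc,
    ssc, strain_condition, batch and rep; no-dye events are excluded.  Events
    with non-positive adjusted fluorescence cannot enter the log-scale model:
    by default they are dropped and their per-condition fraction reported
    (``offset_mode="drop"``); ``offset_mode="shift"`` instead adds the first
    percentile of the positive values to every event.

    The reference condition (default: first in sorted order) anchors the
    per-condition effects at zero.  Random intercepts for batch and rep are
    crossed; if one variance component collapses to zero the model is refit
    without it, with a warning.
    """
    import statsmodels.formula.api as smf

    df = events[~events["is_nodye"]].copy() if "is_nodye" in events.columns else events.copy()
    if "fluor_adj" not in df.columns:
        raise ValueError("events lack fluor_adj; run subtract_autofluorescence first")
    conditions = sorted(df["strain_condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least two strain conditions")
    if df["batch"].nunique() < 2 and df["rep"].nunique() < 2:
        raise ValueError("need at least two levels of batch or rep")
    if reference is None:
        reference = conditions[0]
    elif reference not in conditions:
        raise ValueError(f"reference condition {reference!r} not present")

    positive = df["fluor_adj"] > 0
    excluded = (
        (~positive).groupby(df["strain_condition"]).mean().rename("excluded_fraction")
    )
    if offset_mode == "shift":
        shift = np.percentile(df.loc[positive, "fluor_adj"], 1)
        df["fluor_adj"] = df["fluor_adj"] + shift
        df = df[df["fluor_adj"] > 0]
    elif offset_mode == "drop":
        df = df[positive]
    else:
        raise ValueError(f"unknown offset_mode {offset_mode!r}")

    df = df.assign(
        y=np.log2(df["fluor_adj"]),
        log2_fsc=np.log2(df["fsc"]),
        log2_ssc=np.log2(df["ssc"]),
    ).reset_index(drop=True)
    df["_one"] = 1

    fixed = (
        "y ~ log2_fsc + log2_ssc + "
        f"C(strain_condition, Treatment(reference='{reference}'))"
    )
    vc = {"batch": "0 + C(batch)", "rep": "0 + C(rep)"}

    def _fit(vc_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(fixed, df, groups=df["_one"], vc_formula=vc_formula)
            return model.fit(reml=True, method="lbfgs")

    res = _fit(vc)
    vcomp = dict(zip(res.model.exog_vc.names, np.asarray(res.vcomp)))
    tiny = [k for k, v in vcomp.items() if v < 1e-8]
    if tiny and len(tiny) < len(vc):
        warnings.warn(
            f"variance component(s) {tiny} estimated at zero; refitting without them",
            stacklevel=2,
        )
        vc2 = {k: v for k, v in vc.items() if k not in tiny}
        res = _fit(vc2)
        vcomp = dict(zip(res.model.exog_vc.names, np.asarray(res.vcomp)))

    fe = res.fe_params
    cov = res.cov_params().loc[fe.index, fe.index]
    z = stats.norm.ppf(0.975)

    c = pd.Series(0.0, index=conditions, name="c")
    lo = pd.Series(0.0, index=conditions)
    hi = pd.Series(0.0, index=conditions)
    for cond in conditions:
        if cond == reference:
            continue
        name = f"C(strain_condition, Treatment(reference='{reference}'))[T.{cond}]"
        est = fe[name]
        se = np.sqrt(cov.loc[name, name])
        c[cond] = est
        lo[cond], hi[cond] = est - z * se, est + z * se
    a, b = fe["log2_fsc"], fe["log2_ssc"]
    se_a = np.sqrt(cov.loc["log2_fsc", "log2_fsc"])
    se_b = np.sqrt(cov.loc["log2_ssc", "log2_ssc"])

    return SizeModelFit(
        a=float(a),
        b=float(b),
        c=c,
        c_conf_int=pd.DataFrame({"lower": lo, "upper": hi}),
        a_conf_int=(float(a - z * se_a), float(a + z * se_a)),
        b_conf_int=(float(b - z * se_b), float(b + z * se_b)),
        reference=reference,
        batch_var=float(vcomp.get("batch", 0.0)),
        rep_var=float(vcomp.get("rep", 0.0)),
        resid_var=float(res.scale),
        excluded_fraction=excluded,
        params=fe,
        cov_params=cov,
        converged=bool(res.converged),
    )


def corrected_fluorescence(events: pd.DataFrame, fit: SizeModelFit) -> pd.Series:
    """Per-cell size-corrected log2 fluorescence, for plotting/sorting only.

    ``log2(fluor_adj) - a*log2(fsc) - b*log2(ssc)`` with the cell's own
    scatter values; undefined (NaN) where fluor_adj <= 0.
    """
    fa = events["fluor_adj"].to_numpy(dtype=float)
    out = np.full(len(events), np.nan)
    pos = fa > 0
    out[pos] = (
        np.log2(fa[pos])
        - fit.a * np.log2(events["fsc"].to_numpy(dtype=float)[pos])
        - fit.b * np.log2(events["ssc"].to_numpy(dtype=float)[pos])
    )
    return pd.Series(out, index=events.index, name="log_fluor_corrected")


def contrast_strains(
    fit: SizeModelFit, cond1: str, cond2: str
) -> tuple[float, tuple[float, float], float]:
    """Wald test of c_cond1 - c_cond2 (log2 fluorescence units).

    Returns (estimate, 95% CI, two-sided p).  Identical conditions give
    estimate 0, p = 1.
    """
    for cond in (cond1, cond2):
        if cond not in fit.c.index:
            raise ValueError(f"condition {cond!r} not in fit")
    if cond1 == cond2:
        return 0.0, (0.0, 0.0), 1.0
    vec = pd.Series(0.0, index=fit.params.index)
    n1 = fit.c_param_name(cond1)
    n2 = fit.c_param_name(cond2)
    if n1 is not None:
        vec[n1] = 1.0
    if n2 is not None:
        vec[n2] = -1.0
    est = float(vec @ fit.params)
    se = float(np.sqrt(vec @ fit.cov_params @ vec))
    z = stats.norm.ppf(0.975)
    p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 1.0
    return est, (est - z * se, est + z * se), p


def significance_stars(p: float) -> str:
    """Star mapping used on the figures: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"
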