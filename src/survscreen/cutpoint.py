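"""Optimal-cutpoint dichotomization (Youden index) and Cox power.

The screen dichotomizes each gene at the ROC-optimal threshold for the
overall-survival event indicator, subject to a minimum group-size
constraint, with a small bootstrap reporting the stability of the choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CutoffResult", "PowerResult", "optimal_cutoff", "dichotomize", "cox_power"]


@dataclass
class CutoffResult:
    gene_id: str
    cutoff: float
    sens: float
    spec: float
    youden_j: float
    n_high: int
    n_low: int
    bootstrap_cutoffs: np.ndarray      # NaN where a resample was degenerate
    candidate_cutoffs: np.ndarray      # all constrained Youden maximizers

    @property
    def bootstrap_sd(self) -> float:
        b = self.bootstrap_cutoffs[np.isfinite(self.bootstrap_cutoffs)]
        return float(np.std(b, ddof=1)) if b.size > 1 else np.nan


def _constrained_youden(values: np.ndarray, labels: np.ndarray, min_group_frac: float):
    """Return (thresholds, J, sens, spec) for every constrained candidate.

    Candidate thresholds are midpoints between consecutive distinct values;
    "high" means value > threshold.  Returns empty arrays when no threshold
    keeps both groups at or above ``min_group_frac`` of the sample.
    """
    n = values.size
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = labels[order]
    distinct = np.nonzero(np.diff(v) > 0)[0]  # threshold after position i
    if distinct.size == 0:
        return (np.empty(0),) * 4
    thresholds = (v[distinct] + v[distinct + 1]) / 2.0
    n_low = distinct + 1                      # values <= threshold
    n_high = n - n_low
    min_size = int(np.ceil(min_group_frac * n))
    ok = (n_low >= min_size) & (n_high >= min_size)
    if not np.any(ok):
        return (np.empty(0),) * 4
    thresholds, n_low = thresholds[ok], n_low[ok]
    n_pos = y.sum()
    n_neg = n - n_pos
    cum_pos = np.cumsum(y)[distinct][ok]      # events in the low group
    sens = (n_pos - cum_pos) / n_pos          # events called high
    spec = (n_low - cum_pos) / n_neg          # non-events called low
    return thresholds, sens + spec - 1.0, sens, spec


def _batch_youden_cutoffs(V: np.ndarray, Y: np.ndarray, min_group_frac: float) -> np.ndarray:
    """Constrained Youden-optimal cutoff per row of a (B, n) value matrix.

    Vectorized over rows (bootstrap resamples); applies the same selection
    rule as the scalar path: maximize J, then closest to the row median,
    then lower threshold.  Degenerate rows (one label class, no valid
    threshold) yield NaN.
    """
    B, n = V.shape
    order = np.argsort(V, axis=1, kind="stable")
    v = np.take_along_axis(V, order, axis=1)
    y = np.take_along_axis(Y, order, axis=1)
    thr = (v[:, :-1] + v[:, 1:]) / 2.0
    valid = np.diff(v, axis=1) > 0
    n_low = np.arange(1, n)
    min_size = int(np.ceil(min_group_frac * n))
    valid &= (n_low >= min_size) & ((n - n_low) >= min_size)

    n_pos = y.sum(axis=1, keepdims=True)
    n_neg = n - n_pos
    degenerate = (n_pos == 0) | (n_neg == 0)
    cum_pos = np.cumsum(y, axis=1)[:, :-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = (n_pos - cum_pos) / n_pos
        spec = (n_low[None, :] - cum_pos) / n_neg
    J = np.where(valid, sens + spec - 1.0, -np.inf)
    jmax = J.max(axis=1, keepdims=True)
    cand = valid & np.isclose(J, jmax, rtol=0, atol=1e-12)

    med = np.median(V, axis=1, keepdims=True)
    dist = np.where(cand, np.abs(thr - med), np.inf)
    mind = dist.min(axis=1, keepdims=True)
    pick = np.argmax(cand & (dist == mind), axis=1)
    out = thr[np.arange(B), pick]
    out[degenerate[:, 0] | ~valid.any(axis=1)] = np.nan
    return out


def optimal_cutoff(expression_values, event_labels, min_group_frac: float = 0.2,
                   n_boot: int = 50, seed=None, gene_id: str = "",
                   select: str = "full-sample") -> CutoffResult:
    """ROC-optimal dichotomization threshold for a binary event label.

    Among thresholds keeping at least ``min_group_frac`` of samples in each
    group, pick those maximizing Youden's J (sensitivity + specificity - 1
    for classifying the event); among ties, the one closest to the median
    expression, breaking exact distance ties toward the lower threshold.
    ``n_boot`` bootstrap resamples record the stability of the choice.

    With ``select="full-sample"`` (default) the returned cutoff is the
    full-sample optimum and the bootstrap is reporting-only; with
    ``select="bootstrap-median"`` the returned cutoff is the median of the
    resample optima (snapped to the nearest full-sample candidate
    threshold), an aggregation variant of the same uncertainty device.
    """
    x = np.asarray(expression_values, dtype=float)
    y = np.asarray(event_labels, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    if x.shape != y.shape:
        raise ValueError("expression and labels must have the same length")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("event labels must be binary")
    if y.min() == y.max():
        raise ValueError("event labels are all one class")

    thr, J, sens, spec = _constrained_youden(x, y, min_group_frac)
    if thr.size == 0:
        raise ValueError("no threshold satisfies the group-size constraint")

    jmax = J.max()
    cand = np.isclose(J, jmax, rtol=0, atol=1e-12)
    cand_thr = thr[cand]
    med = np.median(x)
    dist = np.abs(cand_thr - med)
    best_local = np.lexsort((cand_thr, dist))[0]  # min distance, then lower cutoff
    idx = np.nonzero(cand)[0][best_local]

    rng = np.random.default_rng(seed)
    if n_boot > 0:
        take = rng.integers(0, x.size, (n_boot, x.size))
        boot = _batch_youden_cutoffs(x[take], y[take], min_group_frac)
    else:
        boot = np.empty(0)

    if select == "bootstrap-median":
        fin = boot[np.isfinite(boot)]
        if fin.size:
            # snap the bootstrap median onto the nearest admissible threshold
            idx = int(np.argmin(np.abs(thr - np.median(fin))))
    elif select != "full-sample":
        raise ValueError(f"unknown select rule {select!r}")

    n = x.size
    n_low = int(np.sum(x <= thr[idx]))
    return CutoffResult(
        gene_id=gene_id,
        cutoff=float(thr[idx]),
        sens=float(sens[idx]),
        spec=float(spec[idx]),
        youden_j=float(sens[idx] + spec[idx] - 1.0),
        n_high=n - n_low,
        n_low=n_low,
        bootstrap_cutoffs=boot,
        candidate_cutoffs=cand_thr,
    )


def dichotomize(matrix, cutoffs: dict) -> "pd.DataFrame":
    """Binary high/low labels per gene: high iff expression > cutoff.

    ``matrix`` is an :class:`~survscreen.io.ExpressionMatrix`; ``cutoffs``
    maps gene id -> :class:`CutoffResult`.  Returns a genes x samples
    DataFrame of 0/1 integers (1 = high).
    """
    import pandas as pd

    rows = {}
    for gid, cut in cutoffs.items():
        if gid not in matrix.gene_index:
            raise KeyError(f"gene {gid!r} missing from matrix")
        rows[gid] = (matrix.values[matrix.gene_index[gid]] > cut.cutoff).astype(int)
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.sample_ids)


@dataclass
class PowerResult:
    endpoint: str
    n_events: int
    prop_high: float
    log_hr: float
    alpha: float
    power: float


def cox_power(n_events: int, prop_high: float, hr: float,
              alpha: float = 0.05, endpoint: str = "OS") -> PowerResult:
    """Power of the two-sided Wald test for a binary covariate in a Cox model.

    Schoenfeld's formula: power = Phi( sqrt(d * p * (1-p)) * |log hr| - z_{1-a/2} )
    with d events and proportion p in the high group.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0 < prop_high < 1:
        raise ValueError("prop_high must be in (0, 1)")
    if hr <= 0:
        raise ValueError("hr must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    beta = abs(np.log(hr))
    power = float(stats.norm.cdf(np.sqrt(n_events * prop_high * (1 - prop_high)) * beta - z))
    return PowerResult(endpoint=endpoint, n_events=int(n_events), prop_high=float(prop_high),
                       log_hr=float(np.log(hr)), alpha=float(alpha), power=power)
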