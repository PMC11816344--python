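"""Molecular-subtype score clustering and microenvironment score comparison.

Subtype score matrices (MSI / EBV / CIN / GS columns, one row per sample,
e.g. the output of a gastric-cancer expression classifier) are re-clustered
with k-means to discover score-defined subgroups; the cluster with the
highest mean CIN score is labeled "MSI-CIN".  Cell-infiltration score
matrices (precomputed deconvolution estimates) are compared between
expression groups per cohort and intersected across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .association import mann_whitney

__all__ = ["ClusterAssignment", "cluster_subtype_scores", "compare_cell_scores"]

SUBTYPE_COLUMNS = ("MSI", "EBV", "CIN", "GS")


@dataclass
class ClusterAssignment:
    labels: np.ndarray           # 1..k per sample
    k: int
    silhouette: dict             # candidate k -> mean silhouette width
    msi_cin_label: int           # cluster with the highest mean CIN score

    @property
    def msi_cin_mask(self) -> np.ndarray:
        return self.labels == self.msi_cin_label


def cluster_subtype_scores(scores: pd.DataFrame, k_range=range(2, 7),
                           seed: int = 0, n_init: int = 10,
                           standardize: bool = False) -> ClusterAssignment:
    """K-means over subtype scores, k chosen by maximal mean silhouette.

    ``scores`` must contain the four subtype columns.  Scores are used on
    their native scale by default: subtype classifiers emit the four scores
    on one common scale, and z-scoring a score column that carries genuine
    cluster structure inflates its variance estimate and masks exactly the
    separation being sought.  Set ``standardize=True`` for score tables
    mixing heterogeneous scales.
    """
    k_range = list(k_range)
    if min(k_range) < 2:
        raise ValueError("k_range must start at 2 or above")
    missing = [c for c in SUBTYPE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValueError(f"missing subtype columns: {missing}")
    X = scores.loc[:, list(SUBTYPE_COLUMNS)].to_numpy(dtype=float)
    if len(X) < 2 * max(k_range):
        raise ValueError("too few samples for the requested k range")
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValueError("identical score rows: silhouette undefined")
    if standardize:
        sd_safe = np.where(sd == 0, 1.0, sd)
        Xs = (X - X.mean(axis=0)) / sd_safe
    else:
        Xs = X

    sil, fits = {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Xs)
        if np.unique(km.labels_).size < 2:
            continue
        sil[k] = float(silhouette_score(Xs, km.labels_))
        fits[k] = km.labels_
    if not sil:
        raise ValueError("no candidate k produced a valid clustering")
    best = max(sil, key=lambda k: (sil[k], -k))
    labels = fits[best] + 1
    cin_means = {lab: scores["CIN"].to_numpy()[labels == lab].mean()
                 for lab in np.unique(labels)}
    return ClusterAssignment(labels=labels, k=best, silhouette=sil,
                             msi_cin_label=max(cin_means, key=cin_means.get))


def compare_cell_scores(cohorts: list, alpha: float = 0.05):
    """Cross-cohort comparison of cell-score estimates between groups.

    ``cohorts`` is a list of ``(CellScoreMatrix DataFrame, binary group
    labels)``; matrices must share column names.  Per cohort and column a
    two-sided Mann–Whitney compares high vs low with direction = sign of
    the median difference; a column is "common" when p < alpha in every
    cohort with the same direction.  Returns ``(common list, per-cohort
    p-value table)``.

    No multiple-testing correction is applied across columns: robustness
    comes from requiring agreement in every cohort.
    """
    if not cohorts:
        raise ValueError("no cohorts supplied")
    columns = list(cohorts[0][0].columns)
    for df, _ in cohorts[1:]:
        if list(df.columns) != columns:
            raise ValueError("cell-score matrices must share column names")

    rows = []
    for ci, (df, groups) in enumerate(cohorts):
        g = np.asarray(groups).astype(bool)
        if g.size != len(df):
            raise ValueError("group labels must match matrix rows")
        for col in columns:
            v = df[col].to_numpy(dtype=float)
            if np.ptp(v) == 0:
                import logging
                logging.getLogger("survscreen").warning(
                    "column %r constant in cohort %d; excluded", col, ci)
                continue
            hi, lo = v[g], v[~g]
            _, p = mann_whitney(hi, lo)
            diff = np.median(hi) - np.median(lo)
            if diff == 0:
                diff = hi.mean() - lo.mean()
            rows.append({"cohort": ci, "column": col, "p": p,
                         "direction": int(np.sign(diff))})
    table = pd.DataFrame(rows)

    common = []
    n_cohorts = len(cohorts)
    for col, sub in table.groupby("column", sort=False):
        if len(sub) < n_cohorts:
            continue
        if (sub["p"] < alpha).all() and sub["direction"].nunique() == 1 and sub["direction"].iloc[0] != 0:
            common.append(col)
    return sorted(common), table
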