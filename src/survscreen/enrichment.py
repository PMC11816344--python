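"""Preranked gene-set enrichment with permutation significance, plus
meet–min redundancy clustering of enriched pathways.

Genes are ranked by their Spearman correlation with an index gene's
expression; a gene set's enrichment score (ES) is the signed maximum of a
weighted Kolmogorov–Smirnov-type running sum over the ranked list;
significance comes from a gene-label permutation null with
Benjamini–Hochberg FDR across sets.  Redundant enriched sets are grouped by
hierarchical clustering of the meet–min overlap similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet

__all__ = ["RankedList", "EnrichmentResult", "SimilarityMatrix",
           "spearman_rank_metric", "enrichment_score", "enrichment_significance",
           "meet_min", "redundancy_clusters"]


@dataclass
class RankedList:
    gene_ids: list[str]          # ordered by metric, descending
    metric: np.ndarray           # finite, same order

    def __post_init__(self):
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in ranked list")
        self.metric = np.asarray(self.metric, dtype=float)
        if not np.all(np.isfinite(self.metric)):
            raise ValueError("ranking metric must be finite")

    def __len__(self):
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    p: float
    fdr_q: float = np.nan
    n_members: int = 0


@dataclass
class SimilarityMatrix:
    set_names: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.set_names, columns=self.set_names)


def spearman_rank_metric(matrix: ExpressionMatrix, index_gene: str) -> RankedList:
    """Rank all other genes by Spearman correlation with ``index_gene``.

    Ties get average ranks; a constant gene has no defined correlation and
    is recorded as 0 with a warning.
    """
    if index_gene not in matrix.gene_index:
        raise KeyError(f"index gene {index_gene!r} not in matrix")
    if len(matrix.sample_ids) < 3:
        raise ValueError("need at least 3 samples")
    ref = matrix.gene(index_gene)
    ref_r = stats.rankdata(ref)
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix.values)
    ref_c = ref_r - ref_r.mean()
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=1) * (ref_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ ref_c) / denom
    bad = ~np.isfinite(rho)
    if bad.any():
        import logging
        logging.getLogger("survscreen").warning(
            "%d constant genes: correlation undefined, recorded as 0", int(bad.sum()))
        rho[bad] = 0.0
    keep = [i for i, gid in enumerate(matrix.gene_ids) if gid != index_gene]
    order = sorted(keep, key=lambda i: -rho[i])
    return RankedList([matrix.gene_ids[i] for i in order], rho[order])


def _es_from_positions(metric: np.ndarray, hit: np.ndarray, weight_exponent: float) -> float:
    """Signed max deviation of the running sum; ``hit`` is a boolean mask."""
    N = metric.size
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has no members in the ranking")
    if nh == N:
        raise ValueError("gene set covers the entire ranking")
    w = np.abs(metric) ** weight_exponent if weight_exponent != 0 else np.ones(N)
    wh = np.where(hit, w, 0.0)
    denom = wh.sum()
    if denom == 0:
        # all member metrics are exactly zero; fall back to unweighted hits
        wh = hit.astype(float)
        denom = wh.sum()
    steps = wh / denom - (~hit) / (N - nh)
    walk = np.cumsum(steps)
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i])


def enrichment_score(ranked: RankedList, gene_set: GeneSet, weight_exponent: float = 1.0) -> float:
    """Weighted KS-type enrichment score in [-1, 1].

    Hits advance the running sum by |metric|^weight_exponent (normalized
    over hits); misses retreat by 1/(N - Nh); the ES is the signed maximum
    deviation.  ``weight_exponent=0`` gives the classic Kolmogorov–Smirnov
    form.
    """
    hit = np.fromiter((g in gene_set.members for g in ranked.gene_ids),
                      dtype=bool, count=len(ranked))
    return _es_from_positions(ranked.metric, hit, weight_exponent)


def enrichment_significance(ranked: RankedList, sets: list[GeneSet],
                            n_perm: int = 1000, seed=None,
                            weight_exponent: float = 1.0) -> list[EnrichmentResult]:
    """Permutation p-values and BH FDR for a collection of gene sets.

    The null permutes gene labels (equivalently: random member positions of
    the same set size).  p = (1 + #{null ES of the observed sign with
    |ES| >= |observed|}) / (1 + #{null ES of that sign}); BH across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    N = len(ranked)
    metric = ranked.metric
    null_cache: dict[int, np.ndarray] = {}

    results = []
    for gs in sets:
        hit = np.fromiter((g in gs.members for g in ranked.gene_ids), dtype=bool, count=N)
        nh = int(hit.sum())
        obs = _es_from_positions(metric, hit, weight_exponent)
        if nh not in null_cache:
            null = np.empty(n_perm)
            mask = np.zeros(N, dtype=bool)
            for b in range(n_perm):
                mask[:] = False
                mask[rng.choice(N, nh, replace=False)] = True
                null[b] = _es_from_positions(metric, mask, weight_exponent)
            null_cache[nh] = null
        null = null_cache[nh]
        same = null >= 0 if obs >= 0 else null < 0
        p = (1 + int(np.sum(same & (np.abs(null) >= abs(obs))))) / (1 + int(same.sum()))
        results.append(EnrichmentResult(set_name=gs.name, es=obs, p=p, n_members=nh))

    pvals = np.array([r.p for r in results])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, qvals):
        r.fdr_q = float(q)
    return results


def meet_min(set_a, set_b) -> float:
    """Meet–min overlap: |A ∩ B| / min(|A|, |B|)."""
    a = set_a.members if isinstance(set_a, GeneSet) else frozenset(set_a)
    b = set_b.members if isinstance(set_b, GeneSet) else frozenset(set_b)
    if not a or not b:
        raise ValueError("meet_min requires non-empty sets")
    return len(a & b) / min(len(a), len(b))


def redundancy_clusters(sets: list[GeneSet], linkage_method: str = "average",
                        k: int | None = None, height: float | None = None):
    """Group overlapping gene sets by clustering 1 - meet–min distances.

    Agglomerative clustering (average linkage by default) on the meet–min
    similarity matrix, cut either into ``k`` groups or at distance
    ``height``.  Returns ``(labels, SimilarityMatrix, linkage_matrix)``.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 gene sets")
    if k is not None and k > len(sets):
        raise ValueError("k exceeds the number of sets")
    names = [s.name for s in sets]
    n = len(sets)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = meet_min(sets[i], sets[j])
    dist = 1.0 - sim
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    else:
        raise ValueError("give either k or height")
    return labels, SimilarityMatrix(names, sim), Z


def common_enriched(results_by_cohort: list[list[EnrichmentResult]],
                    q_threshold: float = 0.05) -> list[str]:
    """Sets enriched (FDR q < threshold) in every cohort with the same ES sign."""
    per = []
    for results in results_by_cohort:
        per.append({r.set_name: np.sign(r.es) for r in results if r.fdr_q < q_threshold})
    common = set(per[0])
    for d in per[1:]:
        common &= set(d)
    return sorted(s for s in common if len({d[s] for d in per}) == 1)
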