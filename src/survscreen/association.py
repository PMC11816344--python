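"""Clinical-characteristics association tests between expression groups.

Categorical variables are compared with Fisher's exact test (the
Freeman–Halton generalization for r x c tables), continuous variables with
the two-sided Mann–Whitney test, reproducing the layout of a standard
"clinical characteristics by biomarker group" table: counts (%) or median
[IQR] per group, one p-value per variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = ["ContingencyTable", "AssociationRow", "fisher_exact", "mann_whitney",
           "characteristics_table"]

#: relative slack when comparing table probabilities for the two-sided
#: "probability ordering" rule, absorbing float rounding of equal-probability
#: tables.
_P_SLACK = 1 + 1e-7


@dataclass
class ContingencyTable:
    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.counts.sum(axis=1) == 0) or np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("zero margin")


@dataclass
class AssociationRow:
    variable: str
    test: str
    statistic: float
    p: float
    detail: pd.DataFrame | None = None


def _log_table_prob(counts: np.ndarray) -> float:
    """log hypergeometric probability of a table given its margins."""
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    n = counts.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(counts + 1).sum())


def fisher_exact(table) -> float:
    """Two-sided exact test for an r x c contingency table.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's
    (probability-ordering rule).  For 2 x 2 this is Fisher's exact test; for
    larger tables the Freeman–Halton generalization, computed by full
    enumeration over margin-preserving tables.
    """
    if isinstance(table, ContingencyTable):
        counts = table.counts
    else:
        counts = ContingencyTable(
            row_labels=list(range(np.asarray(table).shape[0])),
            col_labels=list(range(np.asarray(table).shape[1])),
            counts=np.asarray(table),
        ).counts
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    logp_obs = _log_table_prob(counts)
    cutoff = logp_obs + np.log(_P_SLACK)

    # enumerate tables row by row; within a row, cell by cell
    r, c = counts.shape
    total = 0.0
    cell = np.zeros((r, c), dtype=int)

    def rec_row(i: int, rem_cols: np.ndarray):
        nonlocal total
        if i == r - 1:
            # last row forced by column margins
            if np.all(rem_cols >= 0):
                cell[i] = rem_cols
                lp = _log_table_prob_fixed(cell, rows, cols)
                if lp <= cutoff:
                    total += np.exp(lp)
            return
        rec_cell(i, 0, rows[i], rem_cols)

    def rec_cell(i: int, j: int, rem_row: int, rem_cols: np.ndarray):
        if j == c - 1:
            if 0 <= rem_row <= rem_cols[j]:
                cell[i, j] = rem_row
                nc = rem_cols.copy()
                nc[j] -= rem_row
                rec_row(i + 1, nc)
            return
        # feasibility bound: remaining cells in this row must absorb rem_row
        hi = min(rem_row, rem_cols[j])
        lo = max(0, rem_row - int(rem_cols[j + 1:].sum()))
        for v in range(lo, hi + 1):
            cell[i, j] = v
            nc = rem_cols.copy()
            nc[j] -= v
            rec_cell(i, j + 1, rem_row - v, nc)

    rec_row(0, cols.copy())
    return float(min(total, 1.0))


def _log_table_prob_fixed(counts, rows, cols) -> float:
    n = rows.sum()
    return float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                 - gammaln(n + 1) - gammaln(counts + 1).sum())


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact distribution for small tie-free samples (both n <= 20), otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def characteristics_table(clin: pd.DataFrame, group_labels, variable_spec: list,
                          group_names: tuple = ("high", "low")) -> tuple[list, pd.DataFrame]:
    """Per-variable group comparison in the style of a clinical Table 1.

    ``variable_spec`` is a list of ``(column, kind)`` with kind
    ``"continuous"`` or ``"categorical"``.  Missing categorical values
    become an explicit "Unknown" level that participates in the test like
    any other level.  Returns the association rows plus a formatted table.
    """
    g = np.asarray(group_labels).astype(bool)
    if g.size != len(clin):
        raise ValueError("group labels must match table length")
    rows_out: list[AssociationRow] = []
    fmt_rows = []
    for var, kind in variable_spec:
        if var not in clin.columns:
            import logging
            logging.getLogger("survscreen").warning("variable %r absent; skipped", var)
            continue
        col = clin[var]
        if kind == "continuous":
            xv = col[g].dropna().to_numpy(dtype=float)
            yv = col[~g].dropna().to_numpy(dtype=float)
            stat, p = mann_whitney(xv, yv)
            rows_out.append(AssociationRow(var, "mann_whitney", stat, p))
            def _miqr(v):
                return f"{np.median(v):.2f}[{np.percentile(v, 25):.2f}, {np.percentile(v, 75):.2f}]"
            fmt_rows.append({"variable": f"{var}, median [IQR]", "level": "",
                             group_names[0]: _miqr(xv), group_names[1]: _miqr(yv),
                             "p": round(p, 3)})
        else:
            lab = col.fillna("Unknown").astype(str)
            levels = sorted(lab.unique())
            counts = np.array([[int(((lab == lv) & g).sum()) for lv in levels],
                               [int(((lab == lv) & ~g).sum()) for lv in levels]]).T
            if len(levels) < 2:
                rows_out.append(AssociationRow(var, "fisher_exact", np.nan, np.nan))
                p = np.nan
            else:
                tab = ContingencyTable(levels, list(group_names), counts)
                p = fisher_exact(tab)
                rows_out.append(AssociationRow(var, "fisher_exact", np.nan, p,
                                               detail=pd.DataFrame(counts, index=levels,
                                                                   columns=group_names)))
            for i, lv in enumerate(levels):
                fmt_rows.append({
                    "variable": f"{var}, n (%)" if i == 0 else "",
                    "level": lv,
                    group_names[0]: f"{counts[i, 0]} ({100 * counts[i, 0] / max(g.sum(), 1):.1f})",
                    group_names[1]: f"{counts[i, 1]} ({100 * counts[i, 1] / max((~g).sum(), 1):.1f})",
                    "p": round(p, 3) if i == 0 and np.isfinite(p) else "",
                })
    return rows_out, pd.DataFrame(fmt_rows)
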