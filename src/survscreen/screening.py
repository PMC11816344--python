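"""Gene-by-gene sequential survival filter chain and two-cohort intersection.

For each gene the screen (1) dichotomizes expression at the constrained
Youden-optimal cutoff for the OS event indicator, (2) requires univariate
Cox significance for both OS and DFS in a consistent direction, (3) requires
multivariate Cox significance after adjusting for age, sex, Lauren class, T
stage, nodal status and primary site, (4) requires the 36-month survival
AUC, sensitivity and specificity at the chosen cutoff to all exceed 0.5,
and (5) requires Schoenfeld power >= 80% for both endpoints.  A gene is a
robust candidate only when it passes in every cohort with the same direction
of effect.

No multiple-testing correction is applied across genes: the screen's
robustness devices are the dual-cohort intersection and the AUC/power gates,
so per-gene p-values are compared directly with the significance level.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cutpoint import CutoffResult, cox_power, optimal_cutoff
from .io import ClinicalRecord, ExpressionMatrix, clinical_frame
from .survival import CoxFit, cox_fit, km_fit, log_rank_multigroup, survival_auc

__all__ = ["ScreenConfig", "FilterTrace", "ScreenResult", "screen_gene",
           "screen_transcriptome", "combined_group_survival"]

STAGES = ("cutoff", "cox_uni", "cox_multi", "auc_gates", "power")

HIGH_WORSE = "high-expression-worse"
HIGH_BETTER = "high-expression-better"


@dataclass
class ScreenConfig:
    alpha: float = 0.05                 # Cox significance level, two-sided
    min_group_frac: float = 0.2
    n_boot: int = 50
    auc_horizon: float = 36.0           # months; "up to 3 years"
    auc_gate: float = 0.5
    sens_gate: float = 0.5
    spec_gate: float = 0.5
    power_threshold: float = 0.8
    adjust_for: tuple = ("age", "sex", "lauren", "t_stage", "nodal", "site")
    seed: int = 0


@dataclass
class FilterTrace:
    """Per-gene, per-cohort record of every screening stage."""

    gene_id: str
    cohort_id: str
    direction: str | None = None
    cutoff: CutoffResult | None = None
    cutoff_ok: bool = False
    cox_os_uni: CoxFit | None = None
    cox_dfs_uni: CoxFit | None = None
    cox_uni_ok: bool = False
    cox_os_multi: CoxFit | None = None
    cox_dfs_multi: CoxFit | None = None
    cox_multi_ok: bool = False
    auc36: float = np.nan
    sens: float = np.nan
    spec: float = np.nan
    auc_gates_ok: bool = False
    power_os: float = np.nan
    power_dfs: float = np.nan
    power_ok: bool = False
    notes: list = field(default_factory=list)

    @property
    def passed_all(self) -> bool:
        return (self.cutoff_ok and self.cox_uni_ok and self.cox_multi_ok
                and self.auc_gates_ok and self.power_ok)

    def stage_flags(self) -> dict:
        return {"cutoff": self.cutoff_ok, "cox_uni": self.cox_uni_ok,
                "cox_multi": self.cox_multi_ok, "auc_gates": self.auc_gates_ok,
                "power": self.power_ok}

    def to_row(self) -> dict:
        def _p(fit, name="group"):
            return fit.summary_row(name)["p"] if fit is not None else np.nan

        def _hr(fit, name="group"):
            return fit.summary_row(name)["hr"] if fit is not None else np.nan

        return {
            "gene": self.gene_id, "cohort": self.cohort_id,
            "direction": self.direction or "",
            "cutoff": self.cutoff.cutoff if self.cutoff else np.nan,
            "cutoff_ok": self.cutoff_ok,
            "hr_os_uni": _hr(self.cox_os_uni), "p_os_uni": _p(self.cox_os_uni),
            "hr_dfs_uni": _hr(self.cox_dfs_uni), "p_dfs_uni": _p(self.cox_dfs_uni),
            "cox_uni_ok": self.cox_uni_ok,
            "hr_os_multi": _hr(self.cox_os_multi), "p_os_multi": _p(self.cox_os_multi),
            "hr_dfs_multi": _hr(self.cox_dfs_multi), "p_dfs_multi": _p(self.cox_dfs_multi),
            "cox_multi_ok": self.cox_multi_ok,
            "auc36": self.auc36, "sens": self.sens, "spec": self.spec,
            "auc_gates_ok": self.auc_gates_ok,
            "power_os": self.power_os, "power_dfs": self.power_dfs,
            "power_ok": self.power_ok, "passed_all": self.passed_all,
        }


def _covariate_design(clin: pd.DataFrame, adjust_for) -> pd.DataFrame:
    """Dummy-coded adjustment design; rare levels (<2 samples) -> Unknown."""
    cols = {}
    for name in adjust_for:
        if name not in clin.columns:
            continue
        col = clin[name]
        if name == "age":
            if col.notna().any():
                cols["age"] = col.fillna(col.median()).astype(float)
            continue
        lab = col.fillna("Unknown").astype(str)
        counts = lab.value_counts()
        rare = counts[counts < 2].index
        lab = lab.where(~lab.isin(rare), "Unknown")
        levels = sorted(lab.unique())
        for lv in levels[1:]:  # drop-first coding
            cols[f"{name}[{lv}]"] = (lab == lv).astype(float)
    design = pd.DataFrame(cols, index=clin.index)
    # drop columns constant in this cohort
    return design.loc[:, design.nunique() > 1]


def _fit_group_cox(times, events, group, extra: pd.DataFrame | None = None) -> CoxFit:
    if extra is None or extra.empty:
        X = np.asarray(group, dtype=float)[:, None]
        names = ["group"]
    else:
        X = np.column_stack([np.asarray(group, dtype=float), extra.to_numpy(dtype=float)])
        names = ["group", *extra.columns]
    return cox_fit(times, events, X, names=names)


def screen_gene(gene_id: str, matrix: ExpressionMatrix, records: list[ClinicalRecord],
                config: ScreenConfig | None = None, cohort_id: str = "",
                clin: pd.DataFrame | None = None,
                design: pd.DataFrame | None = None) -> FilterTrace:
    """Run the five-stage filter chain for one gene in one cohort.

    Short-circuits on the first failed stage; every evaluated stage is
    recorded in the returned trace.  Degenerate genes (constant expression,
    no constrained threshold) fail the cutoff stage without raising.
    """
    config = config or ScreenConfig()
    trace = FilterTrace(gene_id=gene_id, cohort_id=cohort_id)
    if clin is None:
        clin = clinical_frame(records)
    x = matrix.gene(gene_id)
    os_t = clin["os_time"].to_numpy(dtype=float)
    os_e = clin["os_event"].to_numpy(dtype=float)

    # stage 1: constrained Youden cutoff against the OS event indicator
    try:
        cut = optimal_cutoff(x, os_e, min_group_frac=config.min_group_frac,
                             n_boot=config.n_boot,
                             seed=np.random.SeedSequence((config.seed, zlib.crc32(gene_id.encode()))),
                             gene_id=gene_id)
    except ValueError as e:
        trace.notes.append(f"cutoff: {e}")
        return trace
    trace.cutoff = cut
    trace.cutoff_ok = True
    group = (x > cut.cutoff).astype(float)

    # stage 2: univariate Cox, OS then DFS, same direction required
    has_dfs = clin["dfs_time"].notna() & clin["dfs_event"].notna()
    dfs_t = clin.loc[has_dfs, "dfs_time"].to_numpy(dtype=float)
    dfs_e = clin.loc[has_dfs, "dfs_event"].to_numpy(dtype=float)
    dfs_group = group[has_dfs.to_numpy()]
    try:
        fit_os = _fit_group_cox(os_t, os_e, group)
    except ValueError as e:
        trace.notes.append(f"cox_os_uni: {e}")
        return trace
    trace.cox_os_uni = fit_os
    trace.direction = HIGH_WORSE if fit_os.coef[0] > 0 else HIGH_BETTER
    if not (fit_os.p[0] < config.alpha):
        return trace
    try:
        fit_dfs = _fit_group_cox(dfs_t, dfs_e, dfs_group)
    except ValueError as e:
        trace.notes.append(f"cox_dfs_uni: {e}")
        return trace
    trace.cox_dfs_uni = fit_dfs
    if not (fit_dfs.p[0] < config.alpha and fit_dfs.coef[0] * fit_os.coef[0] > 0):
        return trace
    trace.cox_uni_ok = True

    # stage 3: multivariate Cox adjusting for clinical covariates
    if design is None:
        design = _covariate_design(clin, config.adjust_for)
    try:
        fit_os_m = _fit_group_cox(os_t, os_e, group, design)
        trace.cox_os_multi = fit_os_m
        if not (fit_os_m.p[0] < config.alpha):
            return trace
        fit_dfs_m = _fit_group_cox(dfs_t, dfs_e, dfs_group, design.loc[has_dfs])
        trace.cox_dfs_multi = fit_dfs_m
        if not (fit_dfs_m.p[0] < config.alpha):
            return trace
    except ValueError as e:
        trace.notes.append(f"cox_multi: {e}")
        return trace
    trace.cox_multi_ok = True

    # stage 4: 36-month survival AUC / sensitivity / specificity gates,
    # with the marker oriented so that larger values mean higher risk
    sign = 1.0 if trace.direction == HIGH_WORSE else -1.0
    try:
        roc = survival_auc(os_t, os_e, sign * x, min(config.auc_horizon, os_t.max()))
    except ValueError as e:
        trace.notes.append(f"auc: {e}")
        return trace
    trace.auc36 = roc.auc
    trace.sens = roc.sens_at(sign * cut.cutoff)
    trace.spec = roc.spec_at(sign * cut.cutoff)
    if not (trace.auc36 > config.auc_gate and trace.sens > config.sens_gate
            and trace.spec > config.spec_gate):
        return trace
    trace.auc_gates_ok = True

    # stage 5: Schoenfeld power for OS and DFS at the observed effect sizes
    p_high = group.mean()
    trace.power_os = cox_power(int(os_e.sum()), p_high, float(fit_os.hr[0]),
                               alpha=config.alpha, endpoint="OS").power
    trace.power_dfs = cox_power(int(dfs_e.sum()), float(dfs_group.mean()),
                                float(fit_dfs.hr[0]), alpha=config.alpha,
                                endpoint="DFS").power
    trace.power_ok = (trace.power_os >= config.power_threshold
                      and trace.power_dfs >= config.power_threshold)
    return trace


@dataclass
class ScreenResult:
    candidates: dict                 # cohort_id -> {direction -> set of genes}
    intersection: dict               # direction -> sorted gene list
    traces: list[FilterTrace]
    attrition: dict                  # cohort_id -> {stage -> surviving count}

    @property
    def intersection_genes(self) -> list[str]:
        return sorted(set().union(*self.intersection.values())) if self.intersection else []

    def trace_table(self) -> pd.DataFrame:
        return pd.DataFrame([t.to_row() for t in self.traces])


def screen_transcriptome(cohorts: list, config: ScreenConfig | None = None) -> ScreenResult:
    """Screen every shared gene in every cohort and intersect the candidates.

    ``cohorts`` is a list of ``(cohort_id, ExpressionMatrix, records)``
    triples (at least two).  A gene is in the intersection only if it passes
    all five stages in every cohort with the same direction of effect.
    """
    config = config or ScreenConfig()
    if len(cohorts) < 2:
        raise ValueError("screen_transcriptome requires at least 2 cohorts")
    gene_sets = [set(m.gene_ids) for _, m, _ in cohorts]
    shared = sorted(set.intersection(*gene_sets))
    if not shared:
        raise ValueError("cohorts share no gene identifiers")

    traces: list[FilterTrace] = []
    candidates: dict = {}
    attrition: dict = {}
    for cid, matrix, records in cohorts:
        clin = clinical_frame(records)
        design = _covariate_design(clin, config.adjust_for)
        per_dir = {HIGH_WORSE: set(), HIGH_BETTER: set()}
        counts = dict.fromkeys(STAGES, 0)
        for gid in shared:
            t = screen_gene(gid, matrix, records, config, cohort_id=cid,
                            clin=clin, design=design)
            traces.append(t)
            for s, okflag in t.stage_flags().items():
                counts[s] += int(okflag)
            if t.passed_all:
                per_dir[t.direction].add(gid)
        candidates[cid] = per_dir
        attrition[cid] = counts

    inter = {}
    for d in (HIGH_WORSE, HIGH_BETTER):
        common = set.intersection(*(candidates[cid][d] for cid, _, _ in cohorts))
        if common:
            inter[d] = sorted(common)
    return ScreenResult(candidates=candidates, intersection=inter,
                        traces=traces, attrition=attrition)


def combined_group_survival(records: list[ClinicalRecord], factor_a, factor_b,
                            endpoint: str = "os", reference: str | None = None) -> dict:
    """Survival contrasts for the cross of two binary factors.

    Forms the (up to) four combined groups "a0/b0" ... "a1/b1", fits a KM
    curve per non-empty group, an overall log-rank across groups, and a Cox
    model with the combined group as a categorical covariate against
    ``reference`` (default: the "a0/b0" cell).  Contrasts involving an empty
    group are reported as undefined rather than raising.
    """
    clin = clinical_frame(records)
    a = np.asarray(factor_a).astype(int)
    b = np.asarray(factor_b).astype(int)
    if a.size != len(clin) or b.size != len(clin):
        raise ValueError("factors must match the cohort size")
    labels = np.array([f"a{ai}/b{bi}" for ai, bi in zip(a, b)])
    times = clin[f"{endpoint}_time"].to_numpy(dtype=float)
    events = clin[f"{endpoint}_event"].to_numpy(dtype=float)

    present = [g for g in ("a0/b0", "a0/b1", "a1/b0", "a1/b1") if np.any(labels == g)]
    km = {g: km_fit(times[labels == g], events[labels == g]) for g in present}
    lr = log_rank_multigroup(times, events, labels) if len(present) > 1 else None

    reference = reference or present[0]
    contrasts = {}
    others = [g for g in present if g != reference]
    if others:
        X = np.column_stack([(labels == g).astype(float) for g in others])
        try:
            fit = cox_fit(times, events, X, names=others)
            for g in others:
                contrasts[g] = fit.summary_row(g)
        except ValueError:
            pass
    for g in ("a0/b0", "a0/b1", "a1/b0", "a1/b1"):
        if g not in present:
            contrasts[g] = None      # undefined: empty combined group
    return {"groups": present, "km": km, "log_rank": lr,
            "reference": reference, "contrasts": contrasts}
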