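"""Paired synthetic cohorts with the structure the biomarker screen assumes.

The generator emulates a two-cohort MSI gastric-cancer design: two
independent patient sets (default n = 68 each, matching the cohort sizes the
screen is built for), log-scale expression for a transcriptome of null genes
plus a small panel of planted prognostic genes, exponential
proportional-hazards survival for overall survival (OS) and disease-free
survival (DFS), administrative censoring at the follow-up horizon with
uniform dropout calibrated to a target censoring fraction, and categorical
clinical covariates drawn independently of the planted genes (so the
covariates are non-confounding by construction).

Planted genes are bimodal — a "high" and a "low" expression component with
Gaussian within-group noise — so a true dichotomization threshold exists and
the cutpoint stage has a recoverable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import ClinicalRecord, ExpressionMatrix

__all__ = ["SyntheticConfig", "SyntheticCohortPair", "generate_cohort_pair", "generate_score_tables"]


def _default_covariates() -> dict:
    # category frequencies loosely shaped like MSI gastric-cancer tables
    return {
        "sex": {"Female": 0.45, "Male": 0.55},
        "lauren": {"Intestinal": 0.45, "Diffuse": 0.25, "Mixed": 0.08, "Unknown": 0.22},
        "t_stage": {"T1/T2": 0.45, "T3/T4": 0.55},
        "nodal": {"N0": 0.35, "N1/N2/N3": 0.65},
        "site": {"Proximal": 0.35, "Distal": 0.65},
        "age_mean": 67.0,
        "age_sd": 8.0,
    }


@dataclass
class SyntheticConfig:
    """Generator settings; every field is validated at construction."""

    n_samples_per_cohort: int = 68
    n_genes: int = 2000
    n_planted: int = 0
    planted_hr: float | list = 3.5          # hazard ratio high vs low, per planted gene
    planted_high_frac: float = 0.5          # fraction of samples in the high component
    censor_rate: float = 0.3
    followup_horizon: float = 120.0         # months of administrative follow-up
    baseline_hazard: float = 0.005          # events/month for the low-risk group
                                            # (~74% 5-year survival, matching
                                            # favorable-prognosis MSI-GC)
    seed: int = 0
    covariate_spec: dict = field(default_factory=_default_covariates)
    # expression-scale parameters (log2-like scale)
    null_mean_range: tuple = (2.0, 12.0)
    null_sd_range: tuple = (0.3, 1.5)
    planted_low_mean: float = 6.0
    planted_delta: float = 2.0              # separation of the two components
    planted_sd: float = 0.5
    dfs_frac_range: tuple = (0.5, 1.0)      # DFS = OS x U(range) for relapsing samples
    # score-table parameters
    n_cell_scores: int = 119
    n_shifted_scores: int = 5
    cell_score_shift: float = 2.0           # shift in within-group SD units
    cin_frac: float = 0.35                  # fraction in the CIN-like sub-cluster
    cin_separation: float = 5.0             # separation in SD units

    def __post_init__(self):
        if self.n_samples_per_cohort < 1:
            raise ValueError("n_samples_per_cohort must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_planted <= self.n_genes:
            raise ValueError("n_planted must be in [0, n_genes]")
        hrs = self.planted_hrs
        if len(hrs) != self.n_planted:
            raise ValueError("planted_hr must give one hazard ratio per planted gene")
        if any(h <= 0 for h in hrs):
            raise ValueError("planted_hr entries must be positive")
        if not 0.2 < self.planted_high_frac < 0.8:
            raise ValueError("planted_high_frac must lie in (0.2, 0.8)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.followup_horizon <= 0:
            raise ValueError("followup_horizon must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")

    @property
    def planted_hrs(self) -> list[float]:
        hr = self.planted_hr
        if np.isscalar(hr):
            return [float(hr)] * self.n_planted
        return [float(h) for h in hr]

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticCohortPair:
    cohorts: list                    # [(ExpressionMatrix, [ClinicalRecord]), ...]
    ground_truth: dict               # planted genes, true log-HRs, true cutoffs, memberships


def _draw_covariates(rng: np.random.Generator, n: int, spec: dict) -> dict:
    out = {}
    for name in ("sex", "lauren", "t_stage", "nodal", "site"):
        levels = list(spec[name].keys())
        probs = np.asarray(list(spec[name].values()), dtype=float)
        probs = probs / probs.sum()
        out[name] = rng.choice(levels, size=n, p=probs)
    out["age"] = np.round(rng.normal(spec["age_mean"], spec["age_sd"], n), 1)
    return out


def _dropout_prob(config: SyntheticConfig, rates: np.ndarray) -> float:
    """Probability of uniform dropout needed to hit the target censoring rate.

    With event time T ~ Exp(rate) and administrative censoring at the horizon
    F, P(censored | no dropout) = exp(-rate*F) and, for a dropout time drawn
    U(0, F), P(censored | dropout) = (1 - exp(-rate*F)) / (rate*F).  The
    overall censoring probability is linear in the dropout fraction q, so q
    has a closed form (clipped to [0, 1]).
    """
    lf = rates * config.followup_horizon
    b = np.exp(-lf).mean()                      # admin censoring alone
    a = ((1 - np.exp(-lf)) / lf).mean()         # censoring given dropout
    if config.censor_rate < b - 1e-9:
        import logging
        logging.getLogger("survscreen").warning(
            "censor_rate %.2f below the administrative floor %.2f "
            "(followup_horizon x baseline hazard); no dropout added",
            config.censor_rate, b)
    if abs(a - b) < 1e-12:
        return 0.0
    return float(np.clip((config.censor_rate - b) / (a - b), 0.0, 1.0))


def _generate_one(config: SyntheticConfig, rng: np.random.Generator, cohort_id: str):
    n, g = config.n_samples_per_cohort, config.n_genes
    sample_ids = [f"{cohort_id}-{i:04d}" for i in range(n)]
    gene_ids = [f"G{j:05d}" for j in range(g)]
    planted = gene_ids[: config.n_planted]

    # null genes: gene-level mean/SD, independent of survival
    mu = rng.uniform(*config.null_mean_range, g)
    sd = rng.uniform(*config.null_sd_range, g)
    expr = rng.normal(mu[:, None], sd[:, None], (g, n))

    # planted genes: bimodal with a known midpoint threshold
    high = np.zeros((config.n_planted, n), dtype=bool)
    for k in range(config.n_planted):
        high[k] = rng.random(n) < config.planted_high_frac
        expr[k] = config.planted_low_mean + config.planted_delta * high[k] \
            + rng.normal(0.0, config.planted_sd, n)

    log_hrs = np.log(config.planted_hrs)
    eta = high.T.astype(float) @ log_hrs if config.n_planted else np.zeros(n)
    rates = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rates)

    q = _dropout_prob(config, rates)
    dropout = np.where(rng.random(n) < q,
                       rng.uniform(0.0, config.followup_horizon, n),
                       np.inf)
    t_cens = np.minimum(dropout, config.followup_horizon)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    dfs_frac = rng.uniform(*config.dfs_frac_range, n)
    dfs_time = np.where(os_event == 1, os_time * dfs_frac, os_time)
    dfs_event = os_event.copy()

    cov = _draw_covariates(rng, n, config.covariate_spec)
    records = [
        ClinicalRecord(
            sample_id=sample_ids[i],
            os_time=float(os_time[i]), os_event=int(os_event[i]),
            dfs_time=float(dfs_time[i]), dfs_event=int(dfs_event[i]),
            age=float(cov["age"][i]), sex=str(cov["sex"][i]),
            lauren=str(cov["lauren"][i]), t_stage=str(cov["t_stage"][i]),
            nodal=str(cov["nodal"][i]), site=str(cov["site"][i]),
        )
        for i in range(n)
    ]
    matrix = ExpressionMatrix(gene_ids, sample_ids, expr)
    truth = {
        "planted_genes": planted,
        "true_log_hr": log_hrs.tolist(),
        "true_cutoffs": [config.planted_low_mean + config.planted_delta / 2.0] * config.n_planted,
        "high_group": {planted[k]: high[k].astype(int).tolist() for k in range(config.n_planted)},
    }
    return matrix, records, truth


def generate_cohort_pair(config: SyntheticConfig) -> SyntheticCohortPair:
    """Two independent cohorts sharing gene identifiers and planted effects.

    All randomness flows from ``config.seed`` through per-cohort substreams,
    so the same seed reproduces the pair bit for bit.
    """
    streams = np.random.SeedSequence(config.seed).spawn(2)
    cohorts, truths = [], []
    for cid, ss in zip(("A", "B"), streams):
        m, r, t = _generate_one(config, np.random.default_rng(ss), cid)
        cohorts.append((m, r))
        truths.append(t)
    gt = dict(truths[0])
    gt["high_group"] = {"A": truths[0]["high_group"], "B": truths[1]["high_group"]}
    return SyntheticCohortPair(cohorts=cohorts, ground_truth=gt)


def generate_score_tables(config: SyntheticConfig, pair: SyntheticCohortPair):
    """Per-cohort molecular-subtype scores and cell-infiltration scores.

    Subtype scores have four columns (MSI, EBV, CIN, GS); a configurable
    fraction of samples forms a CIN-like sub-cluster whose CIN score is
    shifted by ``cin_separation`` within-group SDs.  The cell-score matrix
    has ``n_cell_scores`` columns, of which the first ``n_shifted_scores``
    are shifted between the first planted gene's high/low groups (no shift
    when no gene is planted).

    Returns a list of ``(subtype_df, cell_df, cin_truth)`` per cohort, where
    ``cin_truth`` is the boolean CIN-cluster membership.
    """
    import pandas as pd

    streams = np.random.SeedSequence((config.seed, 1)).spawn(len(pair.cohorts))
    out = []
    for (matrix, _), ss, cid in zip(pair.cohorts, streams, ("A", "B")):
        rng = np.random.default_rng(ss)
        n = len(matrix.sample_ids)
        cin_member = rng.random(n) < config.cin_frac
        scores = pd.DataFrame(
            {
                "MSI": rng.normal(1.0, 1.0, n),
                "EBV": rng.normal(0.0, 1.0, n),
                "CIN": rng.normal(0.0, 1.0, n) + config.cin_separation * cin_member,
                "GS": rng.normal(0.0, 1.0, n),
            },
            index=matrix.sample_ids,
        )
        cells = rng.normal(0.0, 1.0, (n, config.n_cell_scores))
        if config.n_planted and config.n_shifted_scores:
            high = np.asarray(
                pair.ground_truth["high_group"][cid][pair.ground_truth["planted_genes"][0]],
                dtype=bool,
            )
            cells[:, : config.n_shifted_scores] += config.cell_score_shift * high[:, None]
        cell_df = pd.DataFrame(
            cells, index=matrix.sample_ids,
            columns=[f"sig{j:03d}" for j in range(config.n_cell_scores)],
        )
        out.append((scores, cell_df, cin_member))
    return out
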