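"""Delta expression, effector/memory scores, and per-gene contributions.

For each sample the gene activity vector is baselined against the mean
activity of the day-0 samples of its group (per condition by default), and
the two scores are inner products of that delta vector with the reference
signature weights:

    effector_score[s] = sum_g delta[g, s] * w_eff[g]
    memory_score[s]   = sum_g delta[g, s] * w_mem[g]

Per-gene contribution terms (delta * weight) decompose each score exactly,
and the differential-contribution screen tests, gene by gene, whether the
memory contribution differs between two conditions at a chosen day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .signatures import SignatureVectors, _ranksum_z

log = logging.getLogger(__name__)

BASELINE_POLICIES = ("per_condition_day0", "global_day0")


@dataclass
class DeltaMatrix:
    """Gene x sample activity deltas against day-0 baselines.

    ``baselines`` holds one gene-indexed baseline vector per group (per
    condition, or the single "global" group).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    baseline_policy: str
    baselines: pd.DataFrame  # genes x groups


def delta_expression(
    activity: pd.DataFrame,
    samples: pd.DataFrame,
    policy: str = "per_condition_day0",
) -> DeltaMatrix:
    """Subtract the mean day-0 activity of each sample's baseline group."""
    if policy not in BASELINE_POLICIES:
        raise ValidationError(f"unknown baseline policy {policy!r}")
    samples = samples.set_index("sample_id").loc[list(activity.columns)].reset_index()
    day0 = samples[samples["day"] == 0]
    baselines = {}
    if policy == "per_condition_day0":
        groups = samples["condition"].unique()
        for cond in groups:
            cols = day0.loc[day0["condition"] == cond, "sample_id"]
            if len(cols) == 0:
                raise ValidationError(f"no day-0 samples for condition {cond!r}")
            baselines[cond] = activity[list(cols)].mean(axis=1)
        group_of = samples.set_index("sample_id")["condition"]
    else:
        if len(day0) == 0:
            raise ValidationError("no day-0 samples for global baseline")
        baselines["global"] = activity[list(day0["sample_id"])].mean(axis=1)
        group_of = pd.Series("global", index=samples["sample_id"])
    base_df = pd.DataFrame(baselines)
    delta = activity.sub(
        base_df[group_of.loc[activity.columns]].set_axis(activity.columns, axis=1)
    )
    return DeltaMatrix(delta, samples, policy, base_df)


def _aligned(delta: DeltaMatrix, sig: SignatureVectors):
    shared = delta.values.index.intersection(sig.gene_ids)
    if len(shared) == 0:
        raise ValidationError("no genes shared between delta matrix and signatures")
    n_only_delta = len(delta.values.index) - len(shared)
    n_only_sig = len(sig.gene_ids) - len(shared)
    if n_only_delta or n_only_sig:
        log.info(
            "signature/activity universes: %d shared, %d activity-only, "
            "%d signature-only (contribute 0)",
            len(shared), n_only_delta, n_only_sig,
        )
    return delta.values.loc[shared], sig.weights.loc[shared]


def compute_scores(delta: DeltaMatrix, sig: SignatureVectors) -> pd.DataFrame:
    """Per-sample effector and memory scores (inner products over shared genes)."""
    d, w = _aligned(delta, sig)
    eff = d.to_numpy().T @ w["w_eff"].to_numpy()
    mem = d.to_numpy().T @ w["w_mem"].to_numpy()
    out = delta.samples[["sample_id", "condition", "day"]].copy()
    out["effector_score"] = eff
    out["memory_score"] = mem
    return out


@dataclass
class ContributionTable:
    """Per-gene per-sample contribution terms; columns sum to the scores."""

    c_eff: pd.DataFrame  # genes x samples
    c_mem: pd.DataFrame


def gene_contributions(
    delta: DeltaMatrix, sig: SignatureVectors
) -> ContributionTable:
    """c_eff[g, s] = delta[g, s] * w_eff[g]; likewise c_mem with w_mem."""
    d, w = _aligned(delta, sig)
    return ContributionTable(
        c_eff=d.mul(w["w_eff"], axis=0),
        c_mem=d.mul(w["w_mem"], axis=0),
    )


def differential_contribution(
    contrib: ContributionTable,
    delta: DeltaMatrix,
    samples: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    day: int,
    test: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene screen for memory-contribution differences between conditions.

    At the stated day, per gene: ``delta_between_conditions`` is the mean
    delta in cond_a minus cond_b; the memory/effector contribution
    coordinates are means of c_mem / c_eff over both conditions' samples;
    and a two-sided test (Welch t by default; 'ranksum' available) compares
    c_mem between the two conditions' samples, BH-adjusted. Calls:
    high_memory / low_memory when adjusted p < alpha and c_mem is higher /
    lower in cond_a, else ns.
    """
    cols_a = samples.loc[
        (samples["condition"] == cond_a) & (samples["day"] == day), "sample_id"
    ].tolist()
    cols_b = samples.loc[
        (samples["condition"] == cond_b) & (samples["day"] == day), "sample_id"
    ].tolist()
    if not cols_a or not cols_b:
        raise ValidationError(
            f"no samples for condition/day ({cond_a!r} or {cond_b!r}, day {day})"
        )
    if min(len(cols_a), len(cols_b)) < 2:
        raise ValidationError("need >=2 samples per condition for testing")
    dmean = (
        delta.values[cols_a].mean(axis=1) - delta.values[cols_b].mean(axis=1)
    )
    both = cols_a + cols_b
    mem_coord = contrib.c_mem[both].mean(axis=1)
    eff_coord = contrib.c_eff[both].mean(axis=1)
    a = contrib.c_mem[cols_a].to_numpy()
    b = contrib.c_mem[cols_b].to_numpy()
    if test == "welch":
        tstat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        stat = np.where(np.isnan(tstat), 0.0, tstat)
    elif test == "ranksum":
        stat = _ranksum_z(np.hstack([a, b]), n_a=a.shape[1])
        p = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        raise ValidationError(f"unknown test {test!r}")
    adj = multipletests(p, method="fdr_bh")[1]
    diff_mem = a.mean(axis=1) - b.mean(axis=1)
    call = np.where(
        adj < alpha, np.where(diff_mem > 0, "high_memory", "low_memory"), "ns"
    )
    return pd.DataFrame(
        {
            "delta_between_conditions": dmean,
            "memory_contribution": mem_coord,
            "effector_contribution": eff_coord,
            "statistic": stat,
            "p_value": p,
            "adjusted_p": adj,
            "call": call,
        },
        index=delta.values.index.rename("gene_id"),
    )


def score_timecourse(scores: pd.DataFrame) -> pd.DataFrame:
    """Group means and SEMs of both scores by (condition, day).

    SEM = sd / sqrt(n) with ddof=1; NaN for singleton groups.
    """
    def sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    g = scores.groupby(["condition", "day"], sort=True)
    out = g.agg(
        n=("sample_id", "size"),
        effector_mean=("effector_score", "mean"),
        effector_sem=("effector_score", sem),
        memory_mean=("memory_score", "mean"),
        memory_sem=("memory_score", sem),
    ).reset_index()
    return out
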