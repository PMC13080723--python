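"""Validation experiments: planted-truth recovery, null calibration, determinism.

These routines rerun the whole pipeline on freshly generated synthetic
experiments and measure how well it recovers what was planted. They back
both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses
import filecmp
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_activity import assign_peaks_to_genes, gene_activity_matrix
from .normalize import filter_low_count
from .pipeline import run_pipeline
from .scoring import (
    compute_scores,
    delta_expression,
    differential_contribution,
    gene_contributions,
    score_timecourse,
)
from .signatures import (
    build_signatures,
    log_normalize_reference,
    select_genes,
    state_mean_profiles,
    wilcoxon_deg,
)
from .simulate import (
    GroundTruth,
    SimulationConfig,
    _nbinom,
    simulate_atac_experiment,
    simulate_reference,
)
from .io import ReferenceExpression


def child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds derived from one master seed (all < 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_chain(config: SimulationConfig):
    """Simulate and run the full scoring chain at the study conditions.

    Returns (timecourse, differential-contribution table, truth, scores).
    """
    peaks, genes, counts, samples, truth = simulate_atac_experiment(config)
    ref, _ = simulate_reference(config)
    filtered, _ = filter_low_count(counts)
    pg_map = assign_peaks_to_genes(peaks, genes)
    activity = gene_activity_matrix(filtered, pg_map)
    prof = state_mean_profiles(log_normalize_reference(ref))
    universe = [g for g in prof.means.index if g in set(activity.index)]
    sig = build_signatures(prof, universe=universe)
    delta = delta_expression(activity, samples)
    scores = compute_scores(delta, sig)
    tc = score_timecourse(scores).set_index(["condition", "day"])
    contrib = gene_contributions(delta, sig)
    others = [c for c in config.conditions if c != config.memory_condition]
    cond_b = "BATF" if "BATF" in others else others[0]
    diff = differential_contribution(
        contrib, delta, samples,
        cond_a=config.memory_condition, cond_b=cond_b, day=max(config.days),
    )
    return tc, diff, truth, scores


def trajectory_recovery(seed: int, n_seeds: int = 20,
                        config: SimulationConfig | None = None) -> dict:
    """Fractions of seeds recovering the planted score trajectories.

    Checks, per seed: the memory-score group mean rises strictly across days
    in the planted condition and in no other; the effector-score group mean
    peaks at day 7 in every condition.
    """
    base = config or SimulationConfig()
    memory_ok = effector_ok = 0
    for s in child_seeds(seed, n_seeds):
        cfg = dataclasses.replace(base, seed=s)
        tc, *_ = run_chain(cfg)
        mem_monotone = {}
        eff_peak = {}
        for cond in cfg.conditions:
            m = [tc.loc[(cond, d), "memory_mean"] for d in cfg.days]
            e = [tc.loc[(cond, d), "effector_mean"] for d in cfg.days]
            mem_monotone[cond] = all(a < b for a, b in zip(m, m[1:]))
            eff_peak[cond] = e[1] > e[0] and e[1] > e[2]
        if mem_monotone[cfg.memory_condition] and not any(
            v for c, v in mem_monotone.items() if c != cfg.memory_condition
        ):
            memory_ok += 1
        if all(eff_peak.values()):
            effector_ok += 1
    return {
        "memory_trajectory_rate": memory_ok / n_seeds,
        "effector_day7_peak_rate": effector_ok / n_seeds,
        "n_seeds": n_seeds,
    }


def _two_group_reference(seed: int, n_null: int, n_planted: int,
                         cells_per_group: int, fold: float) -> tuple[
                             ReferenceExpression, list[str], list[str], list[str]]:
    """NB reference with two cell groups; planted genes ``fold``-x in group a."""
    rng = np.random.default_rng(seed)
    n_genes = n_null + n_planted
    genes = [f"g{i:04d}" for i in range(n_genes)]
    planted = sorted(rng.choice(genes, size=n_planted, replace=False)) \
        if n_planted else []
    baseline = rng.lognormal(np.log(2.0), 1.0, size=n_genes)
    mu = np.tile(baseline[:, None], (1, 2 * cells_per_group))
    idx = [genes.index(g) for g in planted]
    mu[idx, :cells_per_group] *= fold
    counts = _nbinom(rng, mu, 0.5).astype(float)
    cells = [f"a{i}" for i in range(cells_per_group)] + [
        f"b{i}" for i in range(cells_per_group)
    ]
    values = pd.DataFrame(counts, index=genes, columns=cells)
    ref = ReferenceExpression(
        values, pd.Series(["other"] * len(cells), index=cells), "raw_counts"
    )
    return ref, planted, cells[:cells_per_group], cells[cells_per_group:]


def marker_selection_recovery(seed: int, n_null: int = 2000,
                              n_planted: int = 100,
                              cells_per_group: int = 300,
                              fold: float = 4.0) -> dict:
    """Planted-marker recovery of the rank-sum screen + selection rule."""
    ref, planted, ga, gb = _two_group_reference(
        seed, n_null, n_planted, cells_per_group, fold
    )
    deg = wilcoxon_deg(log_normalize_reference(ref), ga, gb)
    selected = select_genes(deg, fc_min=2.0, top_n=n_planted)
    return {
        "recovered": len(set(selected) & set(planted)),
        "n_planted": n_planted,
    }


def ranksum_type1_error(seed: int, n_genes: int = 2000,
                        cells_per_group: int = 300,
                        alpha: float = 0.05) -> dict:
    """Empirical type-I rate of the rank-sum p-values on null genes."""
    ref, _, ga, gb = _two_group_reference(seed, n_genes, 0, cells_per_group, 1.0)
    deg = wilcoxon_deg(log_normalize_reference(ref), ga, gb)
    return {
        "type1_error": float((deg["p_value"] < alpha).mean()),
        "n_genes": n_genes,
    }


def contribution_calls(seed: int, planted: bool = True,
                       config: SimulationConfig | None = None) -> dict:
    """Differential-contribution calls on planted or condition-exchangeable data.

    With ``planted=False`` the memory amplitude is zeroed, making every
    condition exchangeable (the effector pulse is shared), so all genes are
    null for the between-condition screen.
    """
    cfg = config or SimulationConfig()
    cfg = dataclasses.replace(
        cfg, seed=seed,
        memory_amplitude=cfg.memory_amplitude if planted else 0.0,
    )
    _, diff, truth, _ = run_chain(cfg)
    out = {
        "ns_fraction": float((diff["call"] == "ns").mean()),
        "n_genes": len(diff),
    }
    if planted:
        mem = [g for g in truth.memory_genes if g in diff.index]
        out["high_memory_recall"] = float(
            (diff.loc[mem, "call"] == "high_memory").mean()
        )
        out["n_memory_genes"] = len(mem)
    return out


def pipeline_determinism(seed: int, work_dir: str | Path) -> dict:
    """Byte-compare artifacts of two full pipeline runs under one seed."""
    work = Path(work_dir)
    dirs = [work / "run1", work / "run2"]
    for d in dirs:
        run_pipeline({"simulate": True, "seed": seed, "out_dir": str(d)})
    names = [
        p.name for p in dirs[0].iterdir()
        if p.is_file() and p.name != "resolved_config.yaml"
    ]
    identical = all(
        filecmp.cmp(dirs[0] / n, dirs[1] / n, shallow=False) for n in names
    )
    return {"identical": identical, "n_artifacts": len(names)}
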