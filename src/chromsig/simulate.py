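"""Synthetic reference and longitudinal ATAC experiment with planted truth.

Two generators mirror the study design the pipeline is built for:

* :func:`simulate_reference` — a labeled single-cell reference with three
  CD8 states (naive, effector, memory) whose mean profiles differ on planted
  gene sets: effector genes are elevated in the effector AND memory states
  (they stay open through the transition), memory genes in the memory state
  only.
* :func:`simulate_atac_experiment` — a donor x condition x day peak-count
  experiment. Effector genes carry a pulse-shaped accessibility shift
  (up at day 7, back to baseline at day 14) in every condition; memory genes
  rise monotonically (0 -> A/2 -> A over days 0/7/14) in one designated
  condition only.

Counts are negative-binomial with log-normal baselines
(var = mu + dispersion * mu^2), multiplicative per-donor and per-library
factors, and a peak-length factor so length normalization is non-trivial.
Every planted shift is recorded in a :class:`GroundTruth` ledger, and the
count emitters consume the ledger's own table, so the ledger is exact by
construction (testable via ``mean_hook``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import io as cio
from .io import PeakSet, ReferenceExpression


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters for both generators.

    Defaults describe a three-donor, duplicated, three-condition CAR-T
    stimulation time course (days 0/7/14) over 2,000 genes with 100 planted
    effector and 100 planted memory genes, at amplitudes of 2.0 and 1.5
    log2 units respectively. Dispersion 0.02 corresponds to a biological
    coefficient of variation of ~14% between duplicates; donor-to-donor
    variability is a separate 10%-CV log-normal baseline effect.
    """

    seed: int = 0
    n_genes: int = 2000
    n_peaks_per_gene: tuple[int, int] = (1, 4)
    n_intergenic_peaks: int = 500
    donors: int = 3
    conditions: tuple[str, ...] = ("untransduced", "BATF", "BATF3")
    days: tuple[int, ...] = (0, 7, 14)
    replicates: int = 2
    effector_gene_count: int = 100
    memory_gene_count: int = 100
    effector_amplitude: float = 2.0  # log2 units
    memory_amplitude: float = 1.5  # log2 units
    memory_condition: str = "BATF3"
    dispersion: float = 0.02  # ATAC counts: var = mu + dispersion * mu^2
    reference_dispersion: float = 0.5  # single-cell reference counts
    library_size_range: tuple[float, float] = (0.8, 1.2)
    cells_per_state: int = 500
    donor_sd: float = 0.1  # log-normal sigma of the donor baseline effect
    peak_length_range: tuple[int, int] = (200, 1000)
    gene_length_range: tuple[int, int] = (2000, 10000)
    intergenic_gap_range: tuple[int, int] = (2000, 6000)
    n_chroms: int = 3
    chrom_length: int | None = None  # None: sized to fit; set to force errors
    baseline_log_mean: float = float(np.log(100.0))  # ATAC peak baseline
    baseline_log_sd: float = 0.8
    ref_baseline_log_mean: float = float(np.log(2.0))  # reference gene baseline
    ref_baseline_log_sd: float = 1.0

    def validate(self) -> None:
        if self.effector_amplitude < 0 or self.memory_amplitude < 0:
            raise ConfigError("amplitudes must be non-negative")
        for name in ("n_genes", "donors", "replicates", "cells_per_state"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.effector_gene_count + self.memory_gene_count > self.n_genes:
            raise ConfigError("planted gene sets exceed n_genes")
        if self.memory_condition not in self.conditions:
            raise ConfigError(
                f"memory_condition {self.memory_condition!r} not in conditions"
            )
        if self.dispersion < 0 or self.reference_dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if 0 not in self.days:
            raise ConfigError("day 0 (baseline) must be among days")


@dataclass
class GroundTruth:
    """Ledger of planted gene sets and the exact shifts the emitters used."""

    effector_genes: list[str]
    memory_genes: list[str]
    #: columns gene_id, condition, day, log2_shift (planted genes only;
    #: every unlisted (gene, condition, day) has shift 0)
    shift_table: pd.DataFrame
    #: columns gene_id, state, log2_shift for the reference generator
    reference_shifts: pd.DataFrame

    def shift_lookup(self) -> dict[tuple[str, str, int], float]:
        return {
            (r.gene_id, r.condition, int(r.day)): float(r.log2_shift)
            for r in self.shift_table.itertuples(index=False)
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effector_genes": self.effector_genes,
            "memory_genes": self.memory_genes,
            "shift_table": self.shift_table.to_dict(orient="records"),
            "reference_shifts": self.reference_shifts.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["effector_genes"],
            payload["memory_genes"],
            pd.DataFrame(
                payload["shift_table"],
                columns=["gene_id", "condition", "day", "log2_shift"],
            ),
            pd.DataFrame(
                payload["reference_shifts"],
                columns=["gene_id", "state", "log2_shift"],
            ),
        )


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB draws parameterized by mean and overdispersion (var = mu + d*mu^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _plant_genes(cfg: SimulationConfig):
    """Planted gene choice shared by both generators (own seed substream)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    picked = rng.choice(
        cfg.n_genes, size=cfg.effector_gene_count + cfg.memory_gene_count,
        replace=False,
    )
    eff = sorted(gene_ids[i] for i in picked[: cfg.effector_gene_count])
    mem = sorted(gene_ids[i] for i in picked[cfg.effector_gene_count:])
    return gene_ids, eff, mem


def simulate_reference(
    config: SimulationConfig,
) -> tuple[ReferenceExpression, GroundTruth]:
    """Generate a labeled three-state reference with planted signature genes.

    Raw NB counts, ``cells_per_state`` cells per state. Effector genes get
    +effector_amplitude (log2) in the effector and memory states; memory
    genes get +memory_amplitude in the memory state only.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gene_ids, eff, mem = _plant_genes(config)
    eff_idx = np.array([gene_ids.index(g) for g in eff], dtype=int)
    mem_idx = np.array([gene_ids.index(g) for g in mem], dtype=int)

    baseline = rng.lognormal(
        config.ref_baseline_log_mean, config.ref_baseline_log_sd, size=config.n_genes
    )
    states = ("naive", "effector", "memory")
    shift = pd.DataFrame(0.0, index=gene_ids, columns=list(states))
    shift.iloc[eff_idx, shift.columns.get_loc("effector")] = config.effector_amplitude
    shift.iloc[eff_idx, shift.columns.get_loc("memory")] = config.effector_amplitude
    shift.iloc[mem_idx, shift.columns.get_loc("memory")] += config.memory_amplitude

    blocks, cells, labels = [], [], []
    for state in states:
        mu = baseline[:, None] * 2.0 ** shift[state].to_numpy()[:, None]
        mu = np.broadcast_to(mu, (config.n_genes, config.cells_per_state))
        blocks.append(_nbinom(rng, mu, config.reference_dispersion))
        cells += [f"{state}_{i:04d}" for i in range(config.cells_per_state)]
        labels += [state] * config.cells_per_state
    values = pd.DataFrame(
        np.hstack(blocks).astype(float), index=gene_ids, columns=cells
    )
    ref = ReferenceExpression(values, pd.Series(labels, index=cells), "raw_counts")

    ref_shifts = (
        shift.loc[sorted(eff) + sorted(mem)]
        .rename_axis("gene_id")
        .reset_index()
        .melt(id_vars="gene_id", var_name="state", value_name="log2_shift")
    )
    truth = GroundTruth(
        effector_genes=eff,
        memory_genes=mem,
        shift_table=pd.DataFrame(
            columns=["gene_id", "condition", "day", "log2_shift"]
        ),
        reference_shifts=ref_shifts,
    )
    return ref, truth


def _build_shift_table(cfg: SimulationConfig, eff: list[str], mem: list[str]):
    rows = []
    for cond in cfg.conditions:
        for day in cfg.days:
            eff_shift = cfg.effector_amplitude if day == 7 else 0.0
            for g in eff:
                rows.append((g, cond, day, eff_shift))
            if cond == cfg.memory_condition:
                if day == 0:
                    mem_shift = 0.0
                elif day == max(cfg.days):
                    mem_shift = cfg.memory_amplitude
                else:
                    mem_shift = cfg.memory_amplitude / 2.0
            else:
                mem_shift = 0.0
            for g in mem:
                rows.append((g, cond, day, mem_shift))
    return pd.DataFrame(rows, columns=["gene_id", "condition", "day", "log2_shift"])


def simulate_atac_experiment(
    config: SimulationConfig,
    mean_hook: Callable[[pd.DataFrame], None] | None = None,
) -> tuple[PeakSet, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the full longitudinal peak-count experiment.

    Returns (peaks, gene models, count matrix, sample sheet, ground truth).
    Genes are laid out without overlap on a synthetic genome; each gene holds
    1..n peaks inside its body and intergenic background peaks fall in the
    gaps, overlapping no gene. ``mean_hook``, if given, receives the exact
    peak x sample NB mean matrix used for sampling.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gene_ids, eff, mem = _plant_genes(config)

    # --- genome layout: genes separated by intergenic gaps, cycling chroms
    glo, ghi = config.gene_length_range
    gap_lo, gap_hi = config.intergenic_gap_range
    gene_rows, gaps = [], []  # gaps: (chrom, start, end) free intervals
    cursors = {f"chr{i + 1}": 0 for i in range(config.n_chroms)}
    chrom_names = list(cursors)
    for i, g in enumerate(gene_ids):
        chrom = chrom_names[i % config.n_chroms]
        gap = int(rng.integers(gap_lo, gap_hi + 1))
        length = int(rng.integers(glo, ghi + 1))
        start = cursors[chrom] + gap
        end = start + length
        if config.chrom_length is not None and end > config.chrom_length:
            raise GenerationError(
                f"genome too small: gene {g} would end at {end} on {chrom} "
                f"(chrom_length={config.chrom_length})"
            )
        gaps.append((chrom, cursors[chrom], start))
        gene_rows.append((g, g, chrom, start, end, "+" if i % 2 == 0 else "-"))
        cursors[chrom] = end
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"]
    )

    # --- peaks inside gene bodies
    plo, phi = config.peak_length_range
    peak_rows, peak_gene = [], []
    for row in genes.itertuples(index=False):
        n_pk = int(rng.integers(config.n_peaks_per_gene[0],
                                config.n_peaks_per_gene[1] + 1))
        for j in range(n_pk):
            length = int(rng.integers(plo, phi + 1))
            start = int(rng.integers(row.start, row.end - length + 1))
            peak_rows.append(
                (f"pk_{row.gene_id}_{j}", row.chrom, start, start + length)
            )
            peak_gene.append(row.gene_id)

    # --- intergenic background peaks, strictly inside gaps
    usable_gaps = [
        (c, s + 1, e - 1) for c, s, e in gaps if (e - 1) - (s + 1) > phi + 2
    ]
    if not usable_gaps and config.n_intergenic_peaks > 0:
        raise GenerationError("no intergenic room for background peaks")
    for j in range(config.n_intergenic_peaks):
        c, s, e = usable_gaps[int(rng.integers(len(usable_gaps)))]
        length = int(rng.integers(plo, phi + 1))
        start = int(rng.integers(s, e - length + 1))
        peak_rows.append((f"pk_bg_{j:04d}", c, start, start + length))
        peak_gene.append(None)
    peaks = PeakSet(
        pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end"])
    )

    # --- sample sheet
    sample_rows = []
    for cond in config.conditions:
        for day in config.days:
            for d in range(1, config.donors + 1):
                for r in range(1, config.replicates + 1):
                    sample_rows.append(
                        (f"{cond}_d{day}_don{d}_r{r}", f"don{d}", cond, day, r)
                    )
    samples = pd.DataFrame(sample_rows, columns=list(cio.SAMPLE_SHEET_COLUMNS))

    # --- NB means: baseline x length factor x donor x library x 2^shift
    truth_shifts = _build_shift_table(config, eff, mem)
    lookup = {
        (r.gene_id, r.condition, int(r.day)): float(r.log2_shift)
        for r in truth_shifts.itertuples(index=False)
    }
    n_peaks, n_samples = len(peak_rows), len(sample_rows)
    baseline = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size=n_peaks
    )
    lengths = peaks.df["end"].to_numpy() - peaks.df["start"].to_numpy()
    mean_len = 0.5 * (plo + phi)
    length_factor = lengths / mean_len
    donor_factor = {
        f"don{d}": rng.lognormal(0.0, config.donor_sd)
        for d in range(1, config.donors + 1)
    }
    lib_lo, lib_hi = config.library_size_range
    lib_factor = rng.uniform(lib_lo, lib_hi, size=n_samples)

    shift_cols = np.zeros((n_peaks, n_samples))
    for s_idx, srow in enumerate(samples.itertuples(index=False)):
        col = np.array([
            lookup.get((g, srow.condition, int(srow.day)), 0.0) if g else 0.0
            for g in peak_gene
        ])
        shift_cols[:, s_idx] = col
    donor_vec = samples["donor"].map(donor_factor).to_numpy()
    mu = (
        baseline[:, None]
        * length_factor[:, None]
        * donor_vec[None, :]
        * lib_factor[None, :]
        * 2.0 ** shift_cols
    )
    if mean_hook is not None:
        mean_hook(
            pd.DataFrame(mu, index=peaks.peak_ids, columns=samples["sample_id"])
        )
    counts = pd.DataFrame(
        _nbinom(rng, mu, config.dispersion),
        index=pd.Index(peaks.peak_ids, name="peak_id"),
        columns=samples["sample_id"].tolist(),
    )

    truth = GroundTruth(
        effector_genes=eff,
        memory_genes=mem,
        shift_table=truth_shifts,
        reference_shifts=pd.DataFrame(columns=["gene_id", "state", "log2_shift"]),
    )
    return peaks, genes, counts, samples, truth


def write_fixture(
    out_dir: str | Path, config: SimulationConfig
) -> dict[str, Path]:
    """Run both generators and write the full fixture set via the io layer."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peaks, genes, counts, samples, truth = simulate_atac_experiment(config)
    ref, ref_truth = simulate_reference(config)
    truth.reference_shifts = ref_truth.reference_shifts
    paths = {
        "peaks": out / "peaks.bed",
        "genes": out / "genes.bed",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "reference_mtx": out / "reference.mtx",
        "reference_genes": out / "reference_genes.txt",
        "reference_cells": out / "reference_cells.txt",
        "reference_labels": out / "reference_labels.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    cio.write_bed(peaks, paths["peaks"])
    cio.write_gene_bed(genes, paths["genes"])
    cio.write_count_matrix(counts, paths["counts"])
    cio.write_sample_sheet(samples, paths["samples"])
    cio.write_reference_mtx(
        ref, paths["reference_mtx"], paths["reference_genes"],
        paths["reference_cells"], paths["reference_labels"],
    )
    truth.to_json(paths["ground_truth"])
    return paths
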