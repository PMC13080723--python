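"""End-to-end orchestration: config validation, staged execution, artifacts.

The pipeline is a pure function of (inputs, config): every stage writes a
TSV artifact whose first line carries the digest of the resolved
configuration, stages log their input/output shapes, and a rerun with the
same config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from . import normalize as nrm
from . import gene_activity as ga
from . import signatures as sig
from . import scoring as sc
from . import simulate as sim

log = logging.getLogger("chromsig")


class ConfigError(ValueError):
    """One or more configuration problems; message lists all of them."""


class PipelineError(RuntimeError):
    pass


#: key -> (type, default). None defaults mean "required unless simulating".
_SCHEMA: dict[str, tuple[type, object]] = {
    "peaks": (str, None),
    "genes": (str, None),
    "gene_format": (str, "bed"),
    "counts": (str, None),
    "samples": (str, None),
    "reference_matrix": (str, None),
    "reference_genes": (str, None),
    "reference_cells": (str, None),
    "reference_labels": (str, None),
    "reference_scale": (str, "raw_counts"),
    "out_dir": (str, "chromsig_out"),
    "simulate": (bool, False),
    "seed": (int, 0),
    "min_mean_raw": (float, nrm.DEFAULT_MIN_MEAN_RAW),
    "library_target": (float, nrm.DEFAULT_LIBRARY_TARGET),
    "n_top_hvp": (int, nrm.DEFAULT_N_TOP_HVP),
    "pca_components": (int, 2),
    "activity_source": (str, "raw"),  # raw (filtered counts) | logged
    "signature_universe": (str, "all"),  # all | deg
    "deg_state_a": (str, "memory"),
    "deg_state_b": (str, "effector"),
    "deg_fc_min": (float, 2.0),
    "deg_top_n": (int, 100),
    "baseline_policy": (str, "per_condition_day0"),
    "diff_test": (str, "welch"),
    "alpha": (float, 0.05),
    "contrast_a": (str, "BATF3"),
    "contrast_b": (str, "BATF"),
    "contrast_day": (int, 14),
}

_CHOICES = {
    "gene_format": ("bed", "gff3"),
    "reference_scale": ("raw_counts", "log_normalized"),
    "activity_source": ("raw", "logged"),
    "signature_universe": ("all", "deg"),
    "baseline_policy": sc.BASELINE_POLICIES,
    "diff_test": ("welch", "ranksum"),
}


@dataclass
class PipelineConfig:
    resolved: dict

    def __getattr__(self, key):
        try:
            return self.resolved[key]
        except KeyError:
            raise AttributeError(key) from None

    @property
    def digest(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        analytic = {k: v for k, v in self.resolved.items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(analytic, sort_keys=True).encode()
        ).hexdigest()[:12]


def validate_config(source: str | Path | dict | None) -> PipelineConfig:
    """Resolve a config mapping (YAML path or dict) against the schema.

    All problems — unknown keys and type errors — are reported together,
    not first-failure. An empty config resolves to all defaults.
    """
    if source is None:
        raw = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{source}: config must be a mapping")
    errors = []
    resolved = {}
    for key, value in raw.items():
        if key not in _SCHEMA:
            errors.append(f"unknown key {key!r}")
    for key, (typ, default) in _SCHEMA.items():
        if key not in raw:
            resolved[key] = default
            continue
        value = raw[key]
        if typ is float and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if typ is int and isinstance(value, bool):
            errors.append(f"key {key!r}: expected int, got bool")
            continue
        if value is not None and not isinstance(value, typ):
            errors.append(
                f"key {key!r}: expected {typ.__name__}, got {type(value).__name__}"
            )
            continue
        if key in _CHOICES and value is not None and value not in _CHOICES[key]:
            errors.append(f"key {key!r}: {value!r} not in {_CHOICES[key]}")
            continue
        resolved[key] = value
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return PipelineConfig(resolved)


def write_table(df: pd.DataFrame, path: Path, digest: str, index: bool = False):
    """Write a result TSV stamped with the resolved-config digest."""
    with open(path, "w") as fh:
        fh.write(f"# config_digest: {digest}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig | dict | str | Path) -> Path:
    """Execute simulate? -> normalize -> gene activity -> signatures ->
    scores -> contributions, writing every stage artifact under out_dir.

    Returns the artifact directory. A stage failure leaves an INCOMPLETE
    marker naming the stage and re-raises as :class:`PipelineError`.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest
    marker = out / "INCOMPLETE"
    stage = "setup"
    try:
        marker.write_text(stage)
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved, fh, sort_keys=True)

        paths = {k: config.resolved[k] for k in (
            "peaks", "genes", "counts", "samples", "reference_matrix",
            "reference_genes", "reference_cells", "reference_labels",
        )}
        if config.simulate:
            stage = "simulate"
            marker.write_text(stage)
            fx = sim.write_fixture(
                out / "fixture", sim.SimulationConfig(seed=config.seed)
            )
            paths = {
                "peaks": fx["peaks"], "genes": fx["genes"],
                "counts": fx["counts"], "samples": fx["samples"],
                "reference_matrix": fx["reference_mtx"],
                "reference_genes": fx["reference_genes"],
                "reference_cells": fx["reference_cells"],
                "reference_labels": fx["reference_labels"],
            }
            log.info("simulate: fixture written under %s", out / "fixture")
        missing = [k for k, v in paths.items() if v is None]
        if missing:
            raise ConfigError(f"missing input path(s): {missing}")

        stage = "load"
        marker.write_text(stage)
        peaks = cio.read_bed(paths["peaks"])
        genes = cio.read_gene_models(paths["genes"], format=config.gene_format)
        counts = cio.read_count_matrix(paths["counts"])
        samples = cio.read_sample_sheet(paths["samples"])
        ref = cio.read_reference_expression(
            paths["reference_matrix"], paths["reference_labels"],
            value_scale=config.reference_scale,
            genes_path=paths["reference_genes"],
            cells_path=paths["reference_cells"],
        )
        log.info("load: %d peaks, %d genes, counts %s, %d samples, reference %s",
                 len(peaks), len(genes), counts.shape, len(samples),
                 ref.values.shape)

        stage = "normalize"
        marker.write_text(stage)
        logged, filtered, removed = nrm.normalize_chain(
            counts, peaks, min_mean_raw=config.min_mean_raw,
            library_target=config.library_target,
        )
        hvp = nrm.select_hvp(logged, n_top=config.n_top_hvp)
        pca = nrm.run_pca(hvp, k=config.pca_components)
        write_table(filtered, out / "filtered_counts.tsv", digest, index=True)
        write_table(logged.values, out / "normalized.tsv", digest, index=True)
        write_table(pca.coordinates, out / "pca.tsv", digest, index=True)
        (out / "provenance.json").write_text(
            json.dumps(logged.provenance, indent=1)
        )
        log.info("normalize: %d peaks removed, logged %s, PCA evr %s",
                 len(removed), logged.values.shape,
                 [round(float(v), 3) for v in pca.explained_variance_ratio])

        stage = "gene_activity"
        marker.write_text(stage)
        pg_map = ga.assign_peaks_to_genes(peaks, genes)
        source = filtered if config.activity_source == "raw" else logged
        activity = ga.gene_activity_matrix(source, pg_map)
        write_table(pg_map.to_table(), out / "peak_gene_map.tsv", digest)
        write_table(activity, out / "gene_activity.tsv", digest, index=True)
        log.info("gene_activity: %d genes x %d samples (source=%s)",
                 *activity.shape, config.activity_source)

        stage = "signatures"
        marker.write_text(stage)
        ref_ln = sig.log_normalize_reference(ref)
        profiles = sig.state_mean_profiles(ref_ln)
        universe = [g for g in profiles.means.index if g in set(activity.index)]
        if config.signature_universe == "deg":
            cells_a = ref_ln.cell_state.index[
                ref_ln.cell_state == config.deg_state_a]
            cells_b = ref_ln.cell_state.index[
                ref_ln.cell_state == config.deg_state_b]
            deg = sig.wilcoxon_deg(ref_ln, cells_a, cells_b)
            write_table(deg, out / "deg.tsv", digest, index=True)
            selected = sig.select_genes(
                deg, fc_min=config.deg_fc_min, top_n=config.deg_top_n
            )
            universe = [g for g in universe if g in set(selected)]
        signatures = sig.build_signatures(profiles, universe=universe)
        write_table(signatures.weights, out / "signatures.tsv", digest, index=True)
        log.info("signatures: universe of %d genes (mode=%s)",
                 len(universe), config.signature_universe)

        stage = "score"
        marker.write_text(stage)
        delta = sc.delta_expression(
            activity, samples, policy=config.baseline_policy
        )
        scores = sc.compute_scores(delta, signatures)
        timecourse = sc.score_timecourse(scores)
        write_table(scores, out / "scores.tsv", digest)
        write_table(timecourse, out / "timecourse.tsv", digest)
        log.info("score: %d samples scored", len(scores))

        stage = "contributions"
        marker.write_text(stage)
        contrib = sc.gene_contributions(delta, signatures)
        diff = sc.differential_contribution(
            contrib, delta, samples,
            cond_a=config.contrast_a, cond_b=config.contrast_b,
            day=config.contrast_day, test=config.diff_test, alpha=config.alpha,
        )
        scatter = diff[
            ["delta_between_conditions", "memory_contribution",
             "effector_contribution", "adjusted_p", "call"]
        ]
        write_table(scatter, out / "contributions.tsv", digest, index=True)
        n_hi = int((diff["call"] == "high_memory").sum())
        n_lo = int((diff["call"] == "low_memory").sum())
        log.info("contributions: %d high_memory, %d low_memory (%s vs %s, day %d)",
                 n_hi, n_lo, config.contrast_a, config.contrast_b,
                 config.contrast_day)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    marker.unlink(missing_ok=True)
    return out
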