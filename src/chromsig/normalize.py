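"""Peak-level normalization chain, low-count filter, HVP selection, PCA.

The chain follows the order: raw counts -> (low-count filter) -> divide by
peak length -> scale each peak by its mean across samples -> library-size
normalize each sample -> log2(x + 1). Each stage stamps its tag and
parameters into the matrix provenance so downstream artifacts are traceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ValidationError, PeakSet

STAGES = ("length_norm", "mean_scaled", "lib_norm", "logged")

DEFAULT_MIN_MEAN_RAW = 10.0
DEFAULT_LIBRARY_TARGET = 1e4
DEFAULT_N_TOP_HVP = 5000


@dataclass
class NormalizedMatrix:
    """Peak x sample real-valued matrix with a pipeline-stage tag.

    ``provenance`` lists the applied operations with their parameters, in
    order; ``flagged`` holds peak ids whose rows were all zero at the
    mean-scaling step (left at 0 rather than divided).
    """

    values: pd.DataFrame
    stage: str
    provenance: list[dict] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite values in normalized matrix")

    def _derive(self, values: pd.DataFrame, stage: str, op: dict,
                flagged: list[str] | None = None) -> "NormalizedMatrix":
        return NormalizedMatrix(
            values, stage, self.provenance + [op],
            self.flagged if flagged is None else flagged,
        )


def filter_low_count(
    counts: pd.DataFrame, min_mean_raw: float = DEFAULT_MIN_MEAN_RAW
) -> tuple[pd.DataFrame, list[str]]:
    """Drop peaks whose mean raw count across samples falls below threshold.

    Applied to the raw count matrix, before length normalization. Returns
    the retained matrix (original order) and the removed peak ids.
    """
    if min_mean_raw < 0:
        raise ValidationError("min_mean_raw must be >= 0")
    means = counts.mean(axis=1)
    keep = means >= min_mean_raw
    if not keep.any():
        raise ValidationError(
            f"low-count filter at {min_mean_raw} removed every peak"
        )
    removed = counts.index[~keep].tolist()
    return counts.loc[keep], removed


def length_normalize(counts: pd.DataFrame, peaks: PeakSet) -> NormalizedMatrix:
    """Counts per kilobase of peak: value[p, s] = count / (length_bp / 1000)."""
    lengths = peaks.lengths()
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValidationError(
            f"peaks missing from PeakSet: {missing[:5].tolist()}"
        )
    kb = lengths.reindex(counts.index).to_numpy() / 1000.0
    values = counts.astype(float).div(kb, axis=0)
    return NormalizedMatrix(
        values, "length_norm", [{"op": "length_normalize", "unit": "kb"}]
    )


def mean_scale(m: NormalizedMatrix) -> NormalizedMatrix:
    """Scale each peak by its mean across samples (row mean becomes 1).

    All-zero rows are left at 0 and their peak ids flagged.
    """
    if m.stage != "length_norm":
        raise ValidationError(f"mean_scale expects stage length_norm, got {m.stage}")
    row_means = m.values.mean(axis=1)
    zero = row_means == 0
    safe = row_means.where(~zero, 1.0)
    values = m.values.div(safe, axis=0)
    return m._derive(
        values, "mean_scaled", {"op": "mean_scale"},
        flagged=m.values.index[zero].tolist(),
    )


def library_normalize(
    m: NormalizedMatrix, target: float = DEFAULT_LIBRARY_TARGET
) -> NormalizedMatrix:
    """Rescale each sample column to sum to ``target``."""
    if m.stage != "mean_scaled":
        raise ValidationError(
            f"library_normalize expects stage mean_scaled, got {m.stage}"
        )
    colsums = m.values.sum(axis=0)
    if (colsums == 0).any():
        bad = colsums.index[colsums == 0][0]
        raise ValidationError(f"sample {bad!r} has an all-zero column")
    values = m.values.div(colsums, axis=1) * target
    return m._derive(
        values, "lib_norm", {"op": "library_normalize", "target": target}
    )


def log_transform(m: NormalizedMatrix) -> NormalizedMatrix:
    """log2(x + 1)."""
    if m.stage != "lib_norm":
        raise ValidationError(f"log_transform expects stage lib_norm, got {m.stage}")
    if (m.values.to_numpy() < 0).any():
        raise ValidationError("negative values before log transform")
    values = np.log2(m.values + 1.0)
    return m._derive(values, "logged", {"op": "log_transform", "base": 2})


def normalize_chain(
    counts: pd.DataFrame,
    peaks: PeakSet,
    min_mean_raw: float = DEFAULT_MIN_MEAN_RAW,
    library_target: float = DEFAULT_LIBRARY_TARGET,
) -> tuple[NormalizedMatrix, pd.DataFrame, list[str]]:
    """Full chain: filter -> length -> mean-scale -> library -> log2.

    Returns the logged matrix, the filtered raw counts, and the removed
    peak ids.
    """
    filtered, removed = filter_low_count(counts, min_mean_raw)
    m = log_transform(
        library_normalize(mean_scale(length_normalize(filtered, peaks)),
                          target=library_target)
    )
    m.provenance.insert(
        0, {"op": "filter_low_count", "min_mean_raw": min_mean_raw,
            "removed": len(removed)},
    )
    return m, filtered, removed


def select_hvp(m: NormalizedMatrix, n_top: int = DEFAULT_N_TOP_HVP) -> NormalizedMatrix:
    """Keep the n_top peaks with largest across-sample variance (logged values).

    Ties break by input order; if n_top >= #peaks this is the identity.
    """
    if m.stage != "logged":
        raise ValidationError(f"select_hvp expects stage logged, got {m.stage}")
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    if n_top >= len(m.values):
        return m._derive(m.values, "logged", {"op": "select_hvp", "n_top": n_top})
    var = m.values.var(axis=1, ddof=0).to_numpy()
    # stable sort on -variance preserves input order among ties
    order = np.argsort(-var, kind="stable")[:n_top]
    keep = np.sort(order)  # original row order
    values = m.values.iloc[keep]
    return m._derive(values, "logged", {"op": "select_hvp", "n_top": n_top})


@dataclass
class PcaResult:
    """Sample coordinates, explained-variance fractions, peak loadings."""

    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # peaks x components


def run_pca(m: NormalizedMatrix, k: int = 2) -> PcaResult:
    """PCA with samples as observations and peaks as centered features.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making results deterministic across backends.
    """
    if m.stage != "logged":
        raise ValidationError(f"run_pca expects stage logged, got {m.stage}")
    n_samples = m.values.shape[1]
    n_feats = m.values.shape[0]
    if k > min(n_samples - 1, n_feats):
        raise ValidationError(
            f"k={k} exceeds min(#samples-1, #peaks) = {min(n_samples - 1, n_feats)}"
        )
    X = m.values.to_numpy().T  # samples x peaks
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    load = pca.components_.T  # peaks x k
    for j in range(k):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] *= -1.0
            coords[:, j] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=m.values.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(load, index=m.values.index, columns=comp_names),
    )
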