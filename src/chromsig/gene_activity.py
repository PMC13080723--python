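"""Peak-to-gene assignment by gene-body overlap and activity aggregation.

A peak is assigned to a gene when the two intervals share at least 1 bp
under half-open arithmetic on the same chromosome; strand is ignored and a
peak may serve several overlapping genes. Gene activity is the arithmetic
mean of the gene's peak values per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import PeakSet, ValidationError
from .normalize import NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class PeakGeneMap:
    """gene_id -> ordered peak ids, plus the reverse peak -> genes index."""

    gene_to_peaks: dict[str, list[str]]
    peak_to_genes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.peak_to_genes:
            rev: dict[str, set[str]] = {}
            for g, pks in self.gene_to_peaks.items():
                for p in pks:
                    rev.setdefault(p, set()).add(g)
            self.peak_to_genes = rev

    def restrict_to_peaks(self, peak_ids) -> "PeakGeneMap":
        """Drop peaks absent from ``peak_ids`` (e.g. removed by filtering)."""
        keep = set(peak_ids)
        g2p = {
            g: [p for p in pks if p in keep]
            for g, pks in self.gene_to_peaks.items()
        }
        dropped_genes = [g for g, pks in g2p.items() if not pks]
        if dropped_genes:
            log.info(
                "%d genes lost all peaks to filtering", len(dropped_genes)
            )
        return PeakGeneMap({g: p for g, p in g2p.items() if p})

    def to_table(self) -> pd.DataFrame:
        rows = [
            (g, p) for g in sorted(self.gene_to_peaks)
            for p in self.gene_to_peaks[g]
        ]
        return pd.DataFrame(rows, columns=["gene_id", "peak_id"])

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "PeakGeneMap":
        g2p: dict[str, list[str]] = {}
        for r in df.itertuples(index=False):
            g2p.setdefault(r.gene_id, []).append(r.peak_id)
        return cls(g2p)


def assign_peaks_to_genes(peaks: PeakSet, genes: pd.DataFrame) -> PeakGeneMap:
    """Map each gene to the peaks overlapping any part of its body.

    Overlap test (half-open): same chrom AND peak.start < gene.end AND
    gene.start < peak.end. Uses an interval tree per chromosome; the result
    equals the all-pairs definition exactly.
    """
    if len(peaks) == 0 or len(genes) == 0:
        log.warning("empty peak set or gene set: empty peak-gene map")
        return PeakGeneMap({})
    trees: dict[str, IntervalTree] = {}
    for row in peaks.df.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.peak_id
        )
    peak_order = {p: i for i, p in enumerate(peaks.peak_ids)}
    g2p: dict[str, list[str]] = {}
    for row in genes.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        hits = sorted(
            (iv.data for iv in tree.overlap(row.start, row.end)),
            key=peak_order.__getitem__,
        )
        if hits:
            g2p[row.gene_id] = hits
    return PeakGeneMap(g2p)


def gene_activity_matrix(
    values: pd.DataFrame | NormalizedMatrix, pg_map: PeakGeneMap
) -> pd.DataFrame:
    """Gene x sample activity: mean over each gene's surviving peaks.

    ``values`` may be the raw (filtered) count matrix or any normalized
    stage; peaks absent from it are first dropped from the map, and genes
    that lose every peak are dropped (logged). Result rows are ordered by
    gene id.
    """
    source_stage = "raw"
    if isinstance(values, NormalizedMatrix):
        source_stage = values.stage
        values = values.values
    restricted = pg_map.restrict_to_peaks(values.index)
    if not restricted.gene_to_peaks:
        log.warning("no genes with surviving peaks: empty activity matrix")
        return pd.DataFrame(
            np.empty((0, values.shape[1])), columns=values.columns
        ).rename_axis("gene_id")
    arr = values.to_numpy(dtype=float)
    row_idx = {p: i for i, p in enumerate(values.index)}
    gene_ids = sorted(restricted.gene_to_peaks)
    out = np.empty((len(gene_ids), values.shape[1]))
    for i, g in enumerate(gene_ids):
        rows = [row_idx[p] for p in restricted.gene_to_peaks[g]]
        out[i] = arr[rows].mean(axis=0)
    result = pd.DataFrame(
        out, index=pd.Index(gene_ids, name="gene_id"), columns=values.columns
    )
    result.attrs["source_stage"] = source_stage
    return result
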