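#!/usr/bin/env python
"""Assign peaks to gene bodies (>=1 bp overlap, strand-agnostic) and average
peak counts per gene into the gene x sample activity matrix.

Writes the peak-gene map and activity matrix under scratch/ and a small
assignment summary under results/.
"""

from pathlib import Path

import pandas as pd

from chromsig import assign_peaks_to_genes, gene_activity_matrix, read_bed, \
    read_count_matrix, read_gene_models
from chromsig.io import write_table

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "scratch" / "fixture"


def main() -> None:
    if not (ROOT / "scratch" / "filtered_counts.tsv").exists():
        raise SystemExit("run analysis/02_normalize_peaks.py first")
    peaks = read_bed(FIXTURE / "peaks.bed")
    genes = read_gene_models(FIXTURE / "genes.bed", format="bed")
    filtered = pd.read_csv(
        ROOT / "scratch" / "filtered_counts.tsv", sep="\t", index_col=0
    )

    pg_map = assign_peaks_to_genes(peaks, genes)
    activity = gene_activity_matrix(filtered, pg_map)

    write_table(pg_map.to_table(), ROOT / "scratch" / "peak_gene_map.tsv")
    write_table(activity, ROOT / "scratch" / "gene_activity.tsv", index=True)

    per_gene = pg_map.to_table().groupby("gene_id").size()
    multi = sum(len(g) > 1 for g in pg_map.peak_to_genes.values())
    summary = pd.DataFrame({
        "quantity": ["genes_with_peaks", "assigned_peaks", "multi_gene_peaks",
                     "mean_peaks_per_gene"],
        "value": [len(pg_map.gene_to_peaks), len(pg_map.peak_to_genes),
                  multi, round(float(per_gene.mean()), 2)],
    })
    write_table(summary, ROOT / "results" / "gene_activity_summary.tsv")
    print(summary.to_string(index=False))
    print(f"activity matrix: {activity.shape[0]} genes x {activity.shape[1]} samples")


if __name__ == "__main__":
    main()
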