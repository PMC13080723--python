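"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals
(the BED convention). GFF3 input, which is 1-based inclusive, is converted
at this boundary and nowhere else.

Tabular readers are thin wrappers over :mod:`pandas` with explicit dialect
and validation contracts; MTX triplets go through :func:`scipy.io.mmread`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(ValueError):
    """Parsed content violates a structural contract (duplicates, ranges...)."""


REQUIRED_STATES = ("naive", "effector", "memory")

#: featureCounts annotation columns, dropped when present in a count matrix
#: header. Detection is by these exact names; anything else is a sample.
FEATURECOUNTS_COLS = {"Chr", "Start", "End", "Strand", "Length"}


# ---------------------------------------------------------------------------
# containers


@dataclass
class PeakSet:
    """Genomic intervals from upstream peak calling.

    ``df`` has columns peak_id, chrom, start, end (0-based half-open);
    peak ids are unique and ``length = end - start`` in base pairs.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.df
        if (d["start"] >= d["end"]).any():
            bad = d.loc[d["start"] >= d["end"], "peak_id"].iloc[0]
            raise ValidationError(f"peak {bad!r} has start >= end")
        if (d["start"] < 0).any():
            raise ValidationError("negative start coordinate")
        if d["peak_id"].duplicated().any():
            dup = d.loc[d["peak_id"].duplicated(), "peak_id"].iloc[0]
            raise ValidationError(f"duplicate peak_id {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def peak_ids(self) -> list[str]:
        return self.df["peak_id"].tolist()

    def lengths(self) -> pd.Series:
        """Peak lengths in bp, indexed by peak_id."""
        d = self.df
        return pd.Series(
            (d["end"] - d["start"]).to_numpy(), index=d["peak_id"].to_numpy()
        )


@dataclass
class ReferenceExpression:
    """Labeled reference expression: genes x cells plus per-cell state labels.

    Cells whose label is outside {naive, effector, memory} are retained in
    ``values`` but excluded from signature construction (``usable`` False).
    """

    values: pd.DataFrame  # genes x cells, non-negative
    cell_state: pd.Series  # index: cell ids; values: state labels
    value_scale: str  # "raw_counts" | "log_normalized"

    def __post_init__(self) -> None:
        if self.value_scale not in ("raw_counts", "log_normalized"):
            raise ValidationError(f"unknown value_scale {self.value_scale!r}")
        missing = set(self.values.columns) - set(self.cell_state.index)
        if missing:
            raise ValidationError(f"cells without a label: {sorted(missing)[:5]}")
        extra = set(self.cell_state.index) - set(self.values.columns)
        if extra:
            raise ValidationError(
                f"label file references unknown cells: {sorted(extra)[:5]}"
            )
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative expression values")

    @property
    def usable(self) -> pd.Series:
        """Boolean per cell: label is one of the three required states."""
        return self.cell_state.isin(REQUIRED_STATES)

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()


# ---------------------------------------------------------------------------
# BED / GFF3


def read_bed(path: str | Path) -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet`.

    Missing names (3-column BED) are generated as ``chrom_start_end``.
    File order is preserved.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            name = parts[3] if len(parts) >= 4 and parts[3] not in ("", ".") else (
                f"{chrom}_{start}_{end}"
            )
            rows.append((name, chrom, start, end))
    df = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])
    return PeakSet(df)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as 4-column BED (round-trips with :func:`read_bed`)."""
    with open(path, "w") as fh:
        for row in peaks.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.peak_id}\n")


def read_gene_models(path: str | Path, format: str = "bed") -> pd.DataFrame:
    """Read gene bodies from BED or GFF3 into a gene-model table.

    Returns a DataFrame with columns gene_id, symbol, chrom, start, end,
    strand; coordinates 0-based half-open. For GFF3 only records of type
    ``gene`` are used and the 1-based inclusive start is shifted by -1.
    """
    if format == "bed":
        peaks = read_bed(path)
        d = peaks.df.rename(columns={"peak_id": "gene_id"})
        # recover strand from column 6 when present
        strands = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                strands.append(parts[5] if len(parts) >= 6 else ".")
        d["strand"] = strands
        d["symbol"] = d["gene_id"]
        out = d[["gene_id", "symbol", "chrom", "start", "end", "strand"]]
    elif format == "gff3":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise ParseError(f"{path}: line {lineno}: fewer than 9 columns")
                if parts[2] != "gene":
                    continue
                try:
                    start1, end1 = int(parts[3]), int(parts[4])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer coordinates"
                    ) from None
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID") or attrs.get("gene_id")
                if not gene_id:
                    raise ValidationError(
                        f"{path}: line {lineno}: gene record missing ID attribute"
                    )
                symbol = attrs.get("Name", gene_id)
                # GFF3 is 1-based inclusive: [start1, end1] -> [start1-1, end1)
                rows.append(
                    (gene_id, symbol, parts[0], start1 - 1, end1, parts[6])
                )
        out = pd.DataFrame(
            rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"]
        )
    else:
        raise ValidationError(f"unknown gene-model format {format!r}")
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r}")
    if len(out) and (out["start"] >= out["end"]).any():
        raise ValidationError("gene with start >= end")
    return out.reset_index(drop=True)


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as BED6."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# count matrix / sample sheet


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a peak-by-sample integer count matrix from TSV.

    The first column holds peak ids. featureCounts output is detected by the
    presence of its annotation columns (Chr/Start/End/Strand/Length), which
    are dropped; every other column is treated as a sample. Comment lines
    starting with ``#`` are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: count matrix needs an id column plus samples")
    id_col = df.columns[0]
    sample_cols = [c for c in df.columns[1:] if c not in FEATURECOUNTS_COLS]
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns found")
    if df[id_col].duplicated().any():
        dup = df.loc[df[id_col].duplicated(), id_col].iloc[0]
        raise ValidationError(f"{path}: duplicate peak id {dup!r}")
    counts = df[sample_cols]
    try:
        mat = counts.astype(np.int64)
    except (ValueError, TypeError):
        # locate the offending cell for the error message
        for col in sample_cols:
            bad = pd.to_numeric(counts[col], errors="coerce")
            if bad.isna().any():
                row = int(np.flatnonzero(bad.isna())[0])
                raise ParseError(
                    f"{path}: non-integer count at row {row + 2}, column {col!r}"
                ) from None
        raise
    if (mat.to_numpy() < 0).any():
        r, c = np.argwhere(mat.to_numpy() < 0)[0]
        raise ParseError(
            f"{path}: negative count at peak {df[id_col].iloc[r]!r}, "
            f"sample {sample_cols[c]!r}"
        )
    mat.index = pd.Index(df[id_col], name="peak_id")
    return mat


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label=counts.index.name or "peak_id")


SAMPLE_SHEET_COLUMNS = ("sample_id", "donor", "condition", "day", "replicate")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample sheet (TSV).

    Required columns: sample_id, donor, condition, day, replicate.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    for col in ("day", "replicate"):
        try:
            df[col] = df[col].astype(int)
        except (ValueError, TypeError):
            raise ParseError(f"{path}: non-integer value in column {col!r}") from None
    if (df["day"] < 0).any():
        raise ValidationError(f"{path}: negative day")
    return df[list(SAMPLE_SHEET_COLUMNS)].reset_index(drop=True)


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference expression


def read_reference_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    value_scale: str = "raw_counts",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ReferenceExpression:
    """Read a gene x cell reference matrix (TSV or MTX triplet) with labels.

    For MTX input, ``genes_path`` and ``cells_path`` (one id per line) name
    the rows and columns. The labels TSV has columns cell_id, state; cells
    labeled outside {naive, effector, memory} are kept but flagged unusable.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValidationError("MTX input requires genes_path and cells_path")
        mat = spio.mmread(matrix_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        genes = [ln.strip() for ln in open(genes_path) if ln.strip()]
        cells = [ln.strip() for ln in open(cells_path) if ln.strip()]
        values = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
    else:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0).astype(float)
        values.index = values.index.astype(str)
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if not {"cell_id", "state"} <= set(labels.columns):
        raise ValidationError(f"{labels_path}: needs columns cell_id, state")
    cell_state = pd.Series(
        labels["state"].to_numpy(), index=labels["cell_id"].to_numpy()
    )
    return ReferenceExpression(values, cell_state, value_scale)


def write_reference_mtx(
    ref: ReferenceExpression, matrix_path: str | Path,
    genes_path: str | Path, cells_path: str | Path, labels_path: str | Path,
) -> None:
    """Write a reference as an MTX triplet plus a labels TSV."""
    spio.mmwrite(str(matrix_path), sparse.csr_matrix(ref.values.to_numpy()))
    Path(genes_path).write_text("".join(f"{g}\n" for g in ref.values.index))
    Path(cells_path).write_text("".join(f"{c}\n" for c in ref.values.columns))
    pd.DataFrame(
        {"cell_id": ref.cell_state.index, "state": ref.cell_state.to_numpy()}
    ).to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic TSV output (fixed dialect: 6 significant digits for reals)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with reals at 6 significant digits."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
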