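"""Readers and writers for every on-disk format the pipeline touches.

All tables are plain text: expression and labels as TSV, annotations and
bins as BED (0-based, half-open), contacts as an upper-triangle triplet
TSV, coordinates as an xyz TSV, truth/metrics/manifest as JSON.  Floats are
written with Python's shortest round-trip repr so write -> read is
bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParseError
from .genome3d import ContactMatrix, Genome3DModel, validate_bins
from .profiling import ExpressionMatrix


def write_expression(m: ExpressionMatrix, path, labels_path=None) -> None:
    """Expression TSV (rows=miRNAs, header=sample ids) + companion labels TSV."""
    df = m.signal.copy()
    df.index.name = "mirna_id"
    df.to_csv(path, sep="\t")
    if labels_path is not None:
        write_labels(m.labels, labels_path)


def write_labels(labels: pd.Series, path) -> None:
    lab = labels.rename("label")
    lab.index.name = "sample_id"
    lab.to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if list(df.columns) != ["sample_id", "label"]:
        raise ParseError(f"{path}: expected columns sample_id, label")
    return pd.Series(df["label"].to_numpy(), index=df["sample_id"])


def read_expression(path, labels_path) -> ExpressionMatrix:
    """Parse expression + labels TSVs; errors carry 1-based line numbers."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip"
    )
    if df.index.duplicated().any():
        pos = int(np.flatnonzero(df.index.duplicated())[0])
        raise ParseError(
            f"{path}:{pos + 2}: duplicate miRNA id {df.index[pos]!r}"
        )
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            pos = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}:{pos + 2}: non-numeric value {df[col].iloc[pos]!r} "
                f"in column {col!r}"
            )
        if vals.isna().any():
            pos = int(np.flatnonzero(vals.isna())[0])
            raise ParseError(f"{path}:{pos + 2}: missing value in column {col!r}")
        df[col] = vals
    labels = read_labels(labels_path)
    if list(labels.index) != list(df.columns):
        raise ParseError(f"{labels_path}: sample ids do not match {path} header")
    return ExpressionMatrix(df, labels)


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """BED6 with one line per record: TSS as [start, start+1), name=miRNA id.

    Multi-mapped miRNAs simply appear on several lines; the reader flags any
    repeated name as non-unique, so the unique flag round-trips.
    """
    with open(path, "w") as fh:
        for rec in annotation.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.tss}\t{rec.tss + 1}\t{rec.mirna_id}\t0\t{rec.strand}\n"
            )


def read_annotation_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{ln}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from None
            if end_i != start_i + 1:
                raise ParseError(f"{path}:{ln}: TSS record must span one base")
            if strand not in "+-":
                raise ParseError(f"{path}:{ln}: bad strand {strand!r}")
            rows.append((name, chrom, start_i, strand))
    df = pd.DataFrame(rows, columns=["mirna_id", "chrom", "tss", "strand"])
    counts = df["mirna_id"].value_counts()
    df["unique"] = df["mirna_id"].map(counts).eq(1)
    return df


def write_bins_bed(bins: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in bins.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.bin_id}\n")


def read_bins_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: expected 4 BED columns")
            try:
                rows.append((int(parts[3]), parts[0], int(parts[1]), int(parts[2])))
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer field") from None
    bins = pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end"])
    return validate_bins(bins.sort_values("bin_id").reset_index(drop=True))


def write_contacts(contacts: ContactMatrix, path) -> None:
    """Upper-triangle triplet TSV (bin_i, bin_j, count), zero pairs omitted."""
    c = contacts.counts
    iu = np.triu_indices(c.shape[0], k=1)
    with open(path, "w") as fh:
        fh.write("bin_i\tbin_j\tcount\n")
        for i, j in zip(*iu):
            if c[i, j] != 0:
                fh.write(f"{i}\t{j}\t{float(c[i, j])!r}\n")


def read_contacts(path, bins: pd.DataFrame) -> ContactMatrix:
    """Materialize the symmetric matrix; conflicting duplicates are errors."""
    n = len(bins)
    counts = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("bin_i"):
            raise ParseError(f"{path}:1: missing triplet header")
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{ln}: expected 3 fields")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{ln}: malformed triplet") from None
            if not (0 <= i < n and 0 <= j < n):
                raise ParseError(f"{path}:{ln}: bin id out of range 0..{n - 1}")
            if i == j:
                if v != 0:
                    raise ParseError(f"{path}:{ln}: nonzero diagonal entry")
                continue
            if seen[i, j] and counts[i, j] != v:
                raise ParseError(
                    f"{path}:{ln}: duplicate pair ({i},{j}) conflicts with "
                    f"earlier value {counts[i, j]!r}"
                )
            counts[i, j] = counts[j, i] = v
            seen[i, j] = seen[j, i] = True
    return ContactMatrix(counts=counts, bins=bins)


def write_coords(model: Genome3DModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_id\tx\ty\tz\n")
        for bid, (x, y, z) in enumerate(model.coords):
            fh.write(f"{bid}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}\n")


def read_coords(path) -> Genome3DModel:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != ["bin_id", "x", "y", "z"]:
        raise ParseError(f"{path}: expected header bin_id, x, y, z")
    if not np.array_equal(df["bin_id"].to_numpy(), np.arange(len(df))):
        raise ParseError(f"{path}: bin_ids must be dense 0..N-1 in order")
    return Genome3DModel(coords=df[["x", "y", "z"]].to_numpy(), stress=0.0)


def write_panel(ids, path) -> None:
    Path(path).write_text("".join(f"{mid}\n" for mid in ids))


def read_panel(path) -> list[str]:
    ids = [ln for ln in Path(path).read_text().splitlines() if ln]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate panel ids")
    return ids


def write_clustering(clustering, path) -> None:
    sizes = clustering.sizes()
    with open(path, "w") as fh:
        fh.write("mirna_id\tcluster_id\tis_singleton\n")
        for mid, cid in clustering.assignments.items():
            fh.write(f"{mid}\t{cid}\t{int(sizes[int(cid)] == 1)}\n")


def write_cluster_scatter(table: pd.DataFrame, clustering, path) -> None:
    """mirna_id, x, y, z, cluster_id export for 3D scatter plots."""
    merged = table.merge(
        clustering.assignments.rename("cluster_id"), left_on="mirna_id", right_index=True
    )
    merged[["mirna_id", "x", "y", "z", "cluster_id"]].to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
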