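"""Readers and writers for the plain-text interchange formats.

Everything is tab-separated text: expression matrices (gene rows, sample
columns), two-column sample-label sidecars, BED6 intervals, GMT gene sets,
three-column weighted PPI edge lists and four-column typed regulatory edge
lists.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ._errors import InputFormatError

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix; first column is the gene identifier."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise InputFormatError(f"{path}: duplicate gene identifiers")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read a 2-column (sample, label) sidecar into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    return df.set_index("sample")["label"]


def write_labels_tsv(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", header=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read BED6 intervals (0-based, half-open); validates coordinates.

    Errors carry the 1-based line number of the offending record.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputFormatError(f"{path}:{lineno}: expected >=4 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise InputFormatError(f"{path}:{lineno}: negative start coordinate")
            if start >= end:
                raise InputFormatError(f"{path}:{lineno}: start must be < end")
            name = parts[3]
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            pathways[parts[0]] = {g for g in parts[2:] if g}
    return pathways


def write_gmt(pathways: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_ppi_tsv(path: str | Path) -> pd.DataFrame:
    """Read a 3-column (node_a, node_b, confidence) PPI edge list."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["node_a", "node_b", "confidence"],
                     dtype={"node_a": str, "node_b": str})
    df["confidence"] = df["confidence"].astype(int)
    return df


def write_ppi_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, ["node_a", "node_b", "confidence"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_regulatory_tsv(path: str | Path) -> pd.DataFrame:
    """Read a 4-column (source, target, edge_type, evidence) edge list."""
    return pd.read_csv(path, sep="\t", header=None,
                       names=["source", "target", "edge_type", "evidence"],
                       dtype=str)


def write_regulatory_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, ["source", "target", "edge_type", "evidence"]].to_csv(
        path, sep="\t", header=False, index=False)
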