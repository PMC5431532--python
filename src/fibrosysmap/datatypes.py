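"""Core in-memory containers for the pipeline.

Matrices are pandas DataFrames with gene (feature) rows and sample columns;
interaction tables are DataFrames with one row per typed edge.  The small
dataclasses here carry the metadata that a bare DataFrame cannot: platform,
units, per-gene direction calls and their supporting studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PLATFORMS = ("microarray", "rnaseq")
UNITS = ("log_intensity", "counts", "rpkm")
NODE_CLASSES = ("TF", "miRNA", "gene")

#: canonical edge-type labels, keyed by (source class, target class)
EDGE_TYPES = {
    ("TF", "gene"): "TF->gene",
    ("TF", "miRNA"): "TF->miRNA",
    ("miRNA", "gene"): "miRNA->gene",
    ("miRNA", "TF"): "miRNA->TF",
}


@dataclass
class ExpressionStudy:
    """One study's genes x samples expression matrix with its metadata.

    ``matrix`` rows are gene identifiers (unique), columns are sample
    identifiers.  ``sample_labels`` maps every column to a condition label
    (e.g. ``IPF``/``control``; NSIP and Sarcoidosis cohorts are also legal).
    RNA-seq studies carry integer read counts plus ``gene_lengths`` (bp) and
    ``library_sizes`` (mapped reads per sample); microarray studies carry
    log-intensities.
    """

    study_id: str
    platform: str
    matrix: pd.DataFrame
    units: str
    sample_labels: pd.Series
    gene_lengths: pd.Series | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        missing = set(self.matrix.columns) - set(self.sample_labels.index)
        if missing:
            raise ValueError(f"samples without a label: {sorted(missing)[:5]}")
        if self.units == "counts" and (self.matrix.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s in self.matrix.columns if self.sample_labels[s] == label]


@dataclass
class ConsensusSet:
    """A named consensus gene signature.

    ``members`` maps gene -> direction ("up"/"down"); ``support`` maps
    gene -> set of study ids whose calls back the membership.
    """

    name: str
    members: dict[str, str] = field(default_factory=dict)
    support: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def genes(self) -> set[str]:
        return set(self.members)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "direction": d,
                "support": ";".join(sorted(self.support.get(g, set()))),
                "n_studies": len(self.support.get(g, set())),
            }
            for g, d in sorted(self.members.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "direction", "support", "n_studies"])


@dataclass
class ClassificationResult:
    """Binary classification/clustering quality summary for one dataset."""

    study_id: str
    n_total: int
    n_case: int
    n_control: int
    n_misclassified: int
    success_rate_pct: float
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_misclassified > self.n_total:
            raise ValueError("misclassified exceeds total")


@dataclass(frozen=True)
class FFLMotif:
    """A 3- or 4-node feed-forward loop.

    ``nodes`` are ordered (TF, miRNA, gene) for 3-node motifs and
    (TF, miRNA, gene1, gene2) with gene1 < gene2 for 4-node motifs.
    ``edges`` are the defining directed edges, sorted for canonical identity.
    """

    nodes: tuple[str, ...]
    node_classes: tuple[str, ...]
    motif_class: str  # TF-FFL | miRNA-FFL | composite-4
    edges: tuple[tuple[str, str], ...]
    p_empirical: float | None = None

    def with_p(self, p: float) -> "FFLMotif":
        return FFLMotif(self.nodes, self.node_classes, self.motif_class, self.edges, p)


@dataclass
class CrosstalkResult:
    """Observed vs null inter-pathway PPI connectivity for one pathway pair."""

    pathway_a: str
    pathway_b: str
    observed_count: int
    null_mean: float
    null_sd: float
    p_empirical: float
    passes_up_up: bool | None = None
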