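"""Per-study differential expression and multi-study consensus signatures.

Two calling rules, matched to platform:

* RNA-seq — expression is converted to RPKM and a gene is called when the
  absolute log2 fold change of group-mean RPKM (with a pseudocount) meets the
  threshold (``|log2FC| >= 1`` by default, boundary inclusive).
* Microarray — a Welch two-sample t-test on per-gene log-intensities, called
  at ``p < alpha``.

Consensus construction combines per-study call tables either by strict
intersection (every study must call the gene, the Set A style) or by the
"shared by at least *k* studies" rule (the Set B style), in both cases
requiring direction agreement unless disabled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConsensusSet, ExpressionStudy

log = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "study_id", "direction", "log2fc", "p_value"]


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``RPKM = count / (length_kb * mapped_millions)``; a zero count maps to
    zero.  ``library_sizes`` is indexed by sample (column) and gives the
    total mapped reads for that sample.

    Raises
    ------
    ValueError
        If a gene has no length, or a length/library size is not positive.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing) > 0:
        raise ValueError(f"missing gene length for: {missing[:5].tolist()}")
    lengths = gene_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene length for: {bad[:5]}")
    libs = library_sizes.loc[counts.columns].astype(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    denom = np.outer(lengths / 1_000.0, libs / 1_000_000.0)
    return counts.astype(float) / denom


def _study_rpkm(study: ExpressionStudy) -> pd.DataFrame:
    if study.units == "rpkm":
        return study.matrix.astype(float)
    if study.units != "counts":
        raise ValueError(f"cannot derive RPKM from units {study.units!r}")
    if study.gene_lengths is None:
        raise ValueError(f"study {study.study_id}: counts without gene lengths")
    libs = study.library_sizes
    if libs is None:
        libs = study.matrix.sum(axis=0)
    return compute_rpkm(study.matrix, study.gene_lengths, libs)


def call_degs(
    study: ExpressionStudy,
    case_label: str = "IPF",
    control_label: str = "control",
    log2fc_min: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Call differentially expressed genes for one study.

    Returns a DataFrame with columns gene, study_id, direction, log2fc,
    p_value (p is NaN for the RNA-seq fold-change rule).  Direction is the
    sign of the case-minus-control difference.

    Microarray genes with zero variance in both groups cannot be tested and
    are excluded with a logged warning.
    """
    case = study.samples_with_label(case_label)
    ctrl = study.samples_with_label(control_label)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"study {study.study_id}: need >=2 samples per group, got "
            f"{len(case)} {case_label!r} and {len(ctrl)} {control_label!r}")

    if study.platform == "rnaseq":
        rpkm = _study_rpkm(study)
        mean_case = rpkm[case].mean(axis=1)
        mean_ctrl = rpkm[ctrl].mean(axis=1)
        log2fc = np.log2(mean_case + pseudocount) - np.log2(mean_ctrl + pseudocount)
        called = log2fc.abs() >= log2fc_min
        out = pd.DataFrame({
            "gene": rpkm.index[called],
            "study_id": study.study_id,
            "direction": np.where(log2fc[called] > 0, "up", "down"),
            "log2fc": log2fc[called].to_numpy(),
            "p_value": np.nan,
        })
    else:
        x = study.matrix[case].to_numpy(float)
        y = study.matrix[ctrl].to_numpy(float)
        testable = ~((x.std(axis=1) == 0) & (y.std(axis=1) == 0))
        n_dropped = int((~testable).sum())
        if n_dropped:
            log.warning("study %s: excluded %d zero-variance genes",
                        study.study_id, n_dropped)
        tres = stats.ttest_ind(x[testable], y[testable], axis=1, equal_var=False)
        diff = x[testable].mean(axis=1) - y[testable].mean(axis=1)
        genes = study.matrix.index[testable]
        called = tres.pvalue < alpha
        out = pd.DataFrame({
            "gene": genes[called],
            "study_id": study.study_id,
            "direction": np.where(diff[called] > 0, "up", "down"),
            "log2fc": diff[called],
            "p_value": tres.pvalue[called],
        })
    return out.reset_index(drop=True)[DEG_COLUMNS]


def _calls_to_directions(calls: pd.DataFrame) -> dict[str, str]:
    """Collapse a per-study call table to gene -> direction (unique genes)."""
    dirs: dict[str, str] = {}
    for gene, direction in zip(calls["gene"], calls["direction"]):
        if gene in dirs and dirs[gene] != direction:
            raise ValueError(f"gene {gene} called in both directions in one study")
        dirs[gene] = direction
    return dirs


def intersect_deg_sets(
    call_tables: list[pd.DataFrame],
    require_same_direction: bool = True,
    name: str = "custom",
) -> ConsensusSet:
    """Strict intersection of per-study DEG calls (the Set A style).

    A gene is a member iff it is called in *every* input table and, when
    ``require_same_direction``, with one direction throughout.
    """
    if len(call_tables) < 2:
        raise ValueError("need at least two DEG collections to intersect")
    per_study = [( _calls_to_directions(t), t["study_id"].iat[0] if len(t) else "?")
                 for t in call_tables]
    common = set(per_study[0][0])
    for dirs, _ in per_study[1:]:
        common &= set(dirs)
    out = ConsensusSet(name=name)
    for gene in sorted(common):
        directions = {dirs[gene] for dirs, _ in per_study}
        if require_same_direction and len(directions) > 1:
            continue
        out.members[gene] = per_study[0][0][gene]
        out.support[gene] = {sid for _, sid in per_study}
    return out


def build_pairwise_consensus(
    call_tables: list[pd.DataFrame],
    min_studies: int = 2,
    name: str = "B",
    conflict_policy: str = "drop",
) -> ConsensusSet:
    """Genes direction-consistently called in >= ``min_studies`` studies
    (the Set B style).

    ``conflict_policy`` controls genes called up in some studies and down in
    others: ``"drop"`` (default) excludes them outright; ``"majority"``
    keeps the direction that alone reaches ``min_studies`` support, still
    dropping ties.
    """
    if min_studies < 2:
        raise ValueError("min_studies must be >= 2")
    if len(call_tables) < min_studies:
        raise ValueError(f"need >= {min_studies} call tables")
    if conflict_policy not in ("drop", "majority"):
        raise ValueError(f"unknown conflict_policy {conflict_policy!r}")

    support: dict[str, dict[str, set[str]]] = {}
    for table in call_tables:
        for gene, direction, sid in zip(
                table["gene"], table["direction"], table["study_id"]):
            support.setdefault(gene, {"up": set(), "down": set()})
            support[gene][direction].add(sid)

    out = ConsensusSet(name=name)
    for gene in sorted(support):
        ups, downs = support[gene]["up"], support[gene]["down"]
        if conflict_policy == "drop" and ups and downs:
            continue
        winner = None
        if len(ups) >= min_studies and len(downs) < min_studies:
            winner = "up"
        elif len(downs) >= min_studies and len(ups) < min_studies:
            winner = "down"
        if winner is None:
            continue
        out.members[gene] = winner
        out.support[gene] = support[gene][winner]
    return out


def consensus_to_tsv(cset: ConsensusSet, path) -> None:
    cset.to_frame().to_csv(path, sep="\t", index=False)
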