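"""Precursor-proxy miRNA expression and consensus DEmiR calling.

Small-RNA sequencing is often unavailable for a disease cohort; when a
long-RNA library still captures reads over miRNA precursor hairpins, the
per-precursor read abundance is a usable proxy for mature miRNA expression.
This module counts reads overlapping precursor intervals (half-open BED
semantics, >=1 bp overlap), converts the counts to RPKM, calls differential
precursors by log2 fold change, builds a multi-study consensus in which
sequencing-based status overrides a contradicting microarray status, and
filters candidate miRNA-target pairs by expression anti-correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .expression import compute_rpkm

log = logging.getLogger(__name__)

MIRNA_COLUMNS = [
    "mirna", "rpkm_case", "rpkm_control", "log2fc", "status", "source", "study_id",
]


def _validate_intervals(df: pd.DataFrame, what: str) -> None:
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    if (starts < 0).any():
        i = int(np.argmax(starts < 0))
        raise ValueError(f"{what} record {i}: negative start coordinate")
    if (starts >= ends).any():
        i = int(np.argmax(starts >= ends))
        raise ValueError(f"{what} record {i}: start must be < end")


def count_precursor_overlaps(
    reads: pd.DataFrame,
    precursors: pd.DataFrame,
    stranded: bool = False,
) -> pd.Series:
    """Count reads overlapping each precursor by >=1 bp (half-open).

    A read counts toward *every* precursor it overlaps; no fractional
    assignment.  When ``stranded``, strand must match, but only for pairs
    where both strands are defined (not ``.``).

    Returns a Series indexed by precursor ``name``.
    """
    _validate_intervals(reads, "read")
    _validate_intervals(precursors, "precursor")

    counts = pd.Series(0, index=precursors["name"].to_numpy(), dtype=int)
    strands = ["+", "-", "."] if stranded else [None]
    for chrom, pre_chrom in precursors.groupby("chrom"):
        chrom_reads = reads[reads["chrom"] == chrom]
        for pre_strand in strands if stranded else [None]:
            if stranded:
                pre_sub = pre_chrom[pre_chrom["strand"] == pre_strand]
                if pre_strand == ".":
                    read_sub = chrom_reads
                else:
                    read_sub = chrom_reads[chrom_reads["strand"].isin([pre_strand, "."])]
            else:
                pre_sub, read_sub = pre_chrom, chrom_reads
            if len(pre_sub) == 0 or len(read_sub) == 0:
                continue
            # a read is either overlapping, entirely left (end <= p.start) or
            # entirely right (start >= p.end); count by exclusion
            read_starts = np.sort(read_sub["start"].to_numpy())
            read_ends = np.sort(read_sub["end"].to_numpy())
            n = len(read_sub)
            left = np.searchsorted(read_ends, pre_sub["start"].to_numpy(), side="right")
            right = n - np.searchsorted(read_starts, pre_sub["end"].to_numpy(), side="left")
            overlap = n - left - right
            counts.loc[pre_sub["name"].to_numpy()] += overlap
    return counts


def proxy_demir_call(
    counts_case: pd.Series,
    counts_control: pd.Series,
    precursor_lengths: pd.Series,
    library_size_case: float,
    library_size_control: float,
    log2fc_min: float = 1.0,
    pseudocount: float = 1.0,
    study_id: str = "rnaseq_proxy",
) -> pd.DataFrame:
    """Call differential precursor-proxy miRNAs from per-condition counts.

    RPKM is computed per condition (library size = total reads in the
    library, not only precursor-overlapping reads); status is ``up``/``down``
    when ``|log2FC| >= log2fc_min`` on pseudocounted RPKM, else
    ``unchanged``.
    """
    missing = counts_case.index.difference(precursor_lengths.index)
    if len(missing) > 0:
        raise ValueError(f"missing precursor length for: {missing[:5].tolist()}")
    case_m = counts_case.to_frame("case")
    ctrl_m = counts_control.reindex(counts_case.index, fill_value=0).to_frame("control")
    libs_case = pd.Series({"case": library_size_case})
    libs_ctrl = pd.Series({"control": library_size_control})
    rpkm_case = compute_rpkm(case_m, precursor_lengths, libs_case)["case"]
    rpkm_ctrl = compute_rpkm(ctrl_m, precursor_lengths, libs_ctrl)["control"]
    log2fc = np.log2(rpkm_case + pseudocount) - np.log2(rpkm_ctrl + pseudocount)
    status = np.where(log2fc >= log2fc_min, "up",
                      np.where(log2fc <= -log2fc_min, "down", "unchanged"))
    return pd.DataFrame({
        "mirna": counts_case.index,
        "rpkm_case": rpkm_case.to_numpy(),
        "rpkm_control": rpkm_ctrl.to_numpy(),
        "log2fc": log2fc.to_numpy(),
        "status": status,
        "source": "rnaseq_proxy",
        "study_id": study_id,
    }).reset_index(drop=True)[MIRNA_COLUMNS]


def consensus_demir(records: pd.DataFrame, min_studies: int = 2) -> pd.DataFrame:
    """Multi-study consensus DEmiR set with sequencing preference.

    A miRNA is retained when at least ``min_studies`` distinct studies agree
    on a changed status (``up`` or ``down``).  Before agreement counting,
    microarray records that contradict a unanimous sequencing-proxy status
    for the same miRNA are discarded (sequencing is preferred on conflict).

    ``records`` needs columns mirna, status, source, study_id; ``unchanged``
    records never contribute support.
    """
    rows = []
    changed = records[records["status"].isin(["up", "down"])]
    for mirna, grp in changed.groupby("mirna"):
        grp = grp.drop_duplicates(subset=["study_id", "status"])
        seq_status = set(grp.loc[grp["source"] == "rnaseq_proxy", "status"])
        if len(seq_status) == 1:
            keep_status = next(iter(seq_status))
            grp = grp[(grp["source"] == "rnaseq_proxy") | (grp["status"] == keep_status)]
        for status, sub in grp.groupby("status"):
            studies = set(sub["study_id"])
            if len(studies) >= min_studies:
                rows.append({
                    "mirna": mirna,
                    "status": status,
                    "n_studies": len(studies),
                    "support": ";".join(sorted(studies)),
                    "source": "rnaseq_proxy" if (sub["source"] == "rnaseq_proxy").any()
                              else "microarray",
                })
    out = pd.DataFrame(rows, columns=["mirna", "status", "n_studies", "support", "source"])
    return out.sort_values("mirna").reset_index(drop=True)


def filter_targets_by_anticorrelation(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    r_max: float = -0.7,
) -> pd.DataFrame:
    """Retain miRNA-target pairs whose Pearson r <= ``r_max`` (boundary
    inclusive).

    ``pairs`` needs columns ``mirna`` and ``gene``; ``expression`` holds one
    row per entity (miRNA or gene) over matched samples.  Pairs with a
    missing or zero-variance profile are dropped with a logged warning.
    """
    kept = []
    for row in pairs.itertuples(index=False):
        m, g = row.mirna, row.gene
        if m not in expression.index or g not in expression.index:
            log.warning("pair (%s, %s): missing expression profile; dropped", m, g)
            continue
        x = expression.loc[m].to_numpy(float)
        y = expression.loc[g].to_numpy(float)
        if len(x) < 3:
            raise ValueError("need >=3 matched samples per pair")
        if x.std() == 0 or y.std() == 0:
            log.warning("pair (%s, %s): zero-variance profile; dropped", m, g)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r <= r_max:
            kept.append({"mirna": m, "gene": g, "r": r})
    return pd.DataFrame(kept, columns=["mirna", "gene", "r"])
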