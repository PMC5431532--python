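"""Synthetic multi-study inputs with the statistical structure the pipeline
assumes.

One master seed expands to independent per-stage child seeds (expression,
regulatory tables, PPI/pathways, precursor reads) via
:class:`numpy.random.SeedSequence`, so each stage regenerates bit-for-bit on
its own.  The generator emulates:

* several case/control studies on two platforms — Gaussian log-intensities
  for microarray, negative-binomial counts (with gene lengths and library
  sizes) for RNA-seq — each covering a random subset of the gene universe,
  with a planted direction-consistent DEG set shifted by a fixed log2 effect;
* typed TF/miRNA/gene regulatory edges in which a configurable "coherent"
  subset carries expression profiles with the expected correlation signs
  (TF-target r > 0, miRNA-target r <= -0.7) and a set of planted
  feed-forward loops;
* a power-law-ish weighted PPI plus random pathways, with planted pathway
  pairs receiving excess inter-pathway edges;
* miRNA precursor intervals and per-condition read alignments with a planted
  differential subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .datatypes import ExpressionStudy
from .io import BED6_COLUMNS

_STAGES = {"expression": 0, "regulatory": 1, "ppi": 2, "reads": 3, "mirna_ma": 4}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic cohort; the defaults are the reference
    study conditions used throughout the test-suite and demo."""

    seed: int = 0
    n_studies: int = 5
    platform_per_study: list[str] = field(default_factory=lambda: [
        "rnaseq", "rnaseq", "microarray", "microarray", "microarray"])
    n_genes: int = 2000
    genes_covered_per_study: float = 0.8
    n_samples_per_group: int = 10
    n_planted_degs: int = 40
    planted_deg_ids: dict[str, str] | None = None  # gene -> up|down
    effect_size: float = 4.0
    noise_sd: float = 0.5
    nb_dispersion: float = 0.1
    include_other_conditions: bool = False

    n_pathways: int = 12
    pathway_size_range: tuple[int, int] = (8, 25)
    planted_crosstalk_pairs: int = 2
    crosstalk_excess_edges: int = 30
    ppi_degree_exponent: float = 2.5
    ppi_mean_degree: float = 8.0

    n_tfs: int = 30
    n_mirnas: int = 40
    edges_per_regulator: int = 8
    coherent_fraction: float = 0.5
    n_profile_samples: int = 20
    n_planted_ffls: int = 5

    n_planted_demirs: int = 10
    demir_fold: float = 4.0
    reads_mean_per_precursor: float = 60.0
    n_background_reads: int = 20000

    def __post_init__(self) -> None:
        if len(self.platform_per_study) != self.n_studies:
            raise ConfigurationError("platform_per_study length must equal n_studies")
        if not 0 < self.genes_covered_per_study <= 1:
            raise ConfigurationError("genes_covered_per_study must be in (0, 1]")
        if self.n_samples_per_group <= 0:
            raise ConfigurationError("n_samples_per_group must be positive")
        if self.pathway_size_range[0] < 1:
            raise ConfigurationError("pathway_size_range must start at >= 1")
        if bad := set(self.platform_per_study) - {"microarray", "rnaseq"}:
            raise ConfigurationError(f"unknown platforms: {sorted(bad)}")
        if self.planted_deg_ids is not None:
            universe = set(self.gene_ids())
            if not set(self.planted_deg_ids) <= universe:
                raise ConfigurationError("planted_deg_ids outside the gene universe")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(self.n_tfs)]

    def mirna_ids(self) -> list[str]:
        return [f"MIR{i:03d}" for i in range(self.n_mirnas)]

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Child generator for one stage, independent of the others."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return np.random.default_rng(children[_STAGES[stage]])

    def planted_degs(self) -> dict[str, str]:
        """Planted DEG directions; chosen from the universe by the
        expression child seed when not given explicitly."""
        if self.planted_deg_ids is not None:
            return dict(self.planted_deg_ids)
        rng = np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STAGES))[0].spawn(1)[0])
        genes = rng.choice(self.gene_ids(), size=self.n_planted_degs, replace=False)
        half = self.n_planted_degs // 2
        return {g: ("up" if i < half else "down") for i, g in enumerate(sorted(genes))}


def generate_expression_studies(config: SyntheticConfig) -> list[ExpressionStudy]:
    """Per-study expression matrices with planted differential genes.

    Case samples are labelled ``IPF`` and controls ``control``; with
    ``include_other_conditions`` each study additionally carries NSIP and
    Sarcoidosis groups whose (distinct) signature reuses the planted genes
    with flipped directions on half of them.
    """
    rng = config.stage_rng("expression")
    genes = config.gene_ids()
    planted = config.planted_degs()

    # gene-level baselines shared across studies
    ma_baseline = pd.Series(rng.normal(8.0, 1.5, config.n_genes), index=genes)
    rna_mu = pd.Series(np.exp(rng.normal(np.log(200.0), 1.0, config.n_genes)), index=genes)
    lengths = pd.Series(rng.integers(500, 5001, config.n_genes), index=genes, name="length")

    other_shift = {}
    if config.include_other_conditions:
        flip = rng.random(len(planted)) < 0.5
        other_shift = {g: (-1 if f else 1) for (g, _), f in zip(sorted(planted.items()), flip)}

    studies = []
    for s, platform in enumerate(config.platform_per_study):
        study_id = f"study{s + 1}"
        n_cov = max(2, int(round(config.genes_covered_per_study * config.n_genes)))
        covered = sorted(rng.choice(genes, size=n_cov, replace=False))
        npg = config.n_samples_per_group
        groups = [("IPF", npg), ("control", npg)]
        if config.include_other_conditions:
            groups += [("NSIP", max(2, npg // 2)), ("Sarcoidosis", max(2, npg // 2))]
        samples, labels = [], []
        for label, n in groups:
            for i in range(n):
                samples.append(f"{study_id}_{label}_{i + 1}")
                labels.append(label)
        labels = pd.Series(labels, index=samples, name="label")

        shift = np.zeros((len(covered), len(samples)))
        for gi, g in enumerate(covered):
            if g not in planted:
                continue
            sgn = 1.0 if planted[g] == "up" else -1.0
            for si, smp in enumerate(samples):
                lab = labels[smp]
                if lab == "IPF":
                    shift[gi, si] = sgn * config.effect_size
                elif lab in ("NSIP", "Sarcoidosis"):
                    shift[gi, si] = sgn * config.effect_size * 0.5 * other_shift.get(g, 1)

        if platform == "microarray":
            base = ma_baseline.loc[covered].to_numpy()[:, None]
            noise = rng.normal(0.0, config.noise_sd, (len(covered), len(samples)))
            matrix = pd.DataFrame(base + shift + noise, index=covered, columns=samples)
            studies.append(ExpressionStudy(
                study_id=study_id, platform="microarray", matrix=matrix,
                units="log_intensity", sample_labels=labels))
        else:
            mu = rna_mu.loc[covered].to_numpy()[:, None] * np.power(2.0, shift)
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu)
            counts = rng.negative_binomial(r, p)
            matrix = pd.DataFrame(counts, index=covered, columns=samples)
            studies.append(ExpressionStudy(
                study_id=study_id, platform="rnaseq", matrix=matrix, units="counts",
                sample_labels=labels, gene_lengths=lengths.loc[covered],
                library_sizes=matrix.sum(axis=0)))
    return studies


def _correlated_profile(base: np.ndarray, target_r: float,
                        rng: np.random.Generator) -> np.ndarray:
    """A profile whose Pearson correlation with ``base`` is >= |target_r| in
    the sign of ``target_r`` (resampled noise until the bound holds)."""
    want_neg = target_r < 0
    for _ in range(200):
        scale = np.sign(target_r)
        y = scale * base + rng.normal(0.0, 0.35, base.shape)
        r = np.corrcoef(base, y)[0, 1]
        if (r <= target_r) if want_neg else (r >= target_r):
            return y
    return np.sign(target_r) * base  # |r| = 1 fallback


def generate_regulatory_tables(
    config: SyntheticConfig,
    studies: list[ExpressionStudy] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Typed regulatory edge table plus matched expression profiles.

    Returns ``(edges, profiles)``: ``edges`` has columns source, target,
    edge_type, evidence; ``profiles`` is an entity x sample matrix over all
    TFs, miRNAs and target genes.  For the coherent subset the target
    profile is resampled so TF-target r > 0 and miRNA-target r <= -0.7; a
    target gene carries at most one coherence constraint, and requesting
    more coherent edges than free targets allow is a configuration error.
    The planted feed-forward loops (TF->miRNA, TF->gene, miRNA->gene) are
    appended with evidence ``planted_ffl``.
    """
    rng = config.stage_rng("regulatory")
    genes, tfs, mirs = config.gene_ids(), config.tf_ids(), config.mirna_ids()
    n_samp = config.n_profile_samples

    profiles = pd.DataFrame(
        rng.normal(0.0, 1.0, (len(tfs) + len(mirs) + len(genes), n_samp)),
        index=tfs + mirs + genes,
        columns=[f"P{i + 1}" for i in range(n_samp)],
    )

    rows: list[tuple[str, str, str, str]] = []
    seen: set[tuple[str, str]] = set()

    def add_edge(src, tgt, etype, evidence):
        if (src, tgt) not in seen:
            seen.add((src, tgt))
            rows.append((src, tgt, etype, evidence))

    for tf in tfs:
        n_mir_targets = min(rng.binomial(config.edges_per_regulator, 0.2), len(mirs))
        targets_g = rng.choice(genes, size=config.edges_per_regulator - n_mir_targets,
                               replace=False)
        targets_m = rng.choice(mirs, size=n_mir_targets, replace=False)
        for g in targets_g:
            add_edge(tf, g, "TF->gene", "synthetic")
        for m in targets_m:
            add_edge(tf, m, "TF->miRNA", "synthetic")
    for m in mirs:
        n_tf_targets = min(rng.binomial(config.edges_per_regulator, 0.1), len(tfs))
        targets_g = rng.choice(genes, size=config.edges_per_regulator - n_tf_targets,
                               replace=False)
        targets_t = rng.choice(tfs, size=n_tf_targets, replace=False)
        for g in targets_g:
            add_edge(m, g, "miRNA->gene", "synthetic")
        for t in targets_t:
            add_edge(m, t, "miRNA->TF", "synthetic")

    for i in range(config.n_planted_ffls):
        tf = tfs[i % len(tfs)]
        m = mirs[i % len(mirs)]
        g = genes[-(i + 1)]
        add_edge(tf, m, "TF->miRNA", "planted_ffl")
        add_edge(tf, g, "TF->gene", "planted_ffl")
        add_edge(m, g, "miRNA->gene", "planted_ffl")

    edges = pd.DataFrame(rows, columns=["source", "target", "edge_type", "evidence"])

    # impose coherence constraints on gene-targeting edges
    gene_edges = edges[edges["edge_type"].isin(["TF->gene", "miRNA->gene"])]
    n_coherent = int(round(config.coherent_fraction * len(gene_edges)))
    constrained: set[str] = set()
    coherent_flags = []
    n_done = 0
    order = rng.permutation(len(gene_edges))
    for pos in order:
        row = gene_edges.iloc[pos]
        if n_done >= n_coherent or row.target in constrained:
            coherent_flags.append((gene_edges.index[pos], False))
            continue
        base = profiles.loc[row.source].to_numpy()
        target_r = -0.7 if row.edge_type == "miRNA->gene" else 0.5
        profiles.loc[row.target] = _correlated_profile(base, target_r, rng)
        constrained.add(row.target)
        coherent_flags.append((gene_edges.index[pos], True))
        n_done += 1
    if n_done < n_coherent:
        raise ConfigurationError(
            f"only {n_done} coherent edges possible (targets exhausted), "
            f"{n_coherent} requested")
    coherent = pd.Series(False, index=edges.index)
    for idx, flag in coherent_flags:
        coherent.loc[idx] = flag
    edges["evidence"] = np.where(
        coherent & (edges["evidence"] == "synthetic"), "coherent", edges["evidence"])
    return edges, profiles


def node_classes_for(config: SyntheticConfig) -> dict[str, str]:
    classes = {g: "gene" for g in config.gene_ids()}
    classes.update({t: "TF" for t in config.tf_ids()})
    classes.update({m: "miRNA" for m in config.mirna_ids()})
    return classes


def generate_ppi_and_pathways(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict[str, set[str]], list[tuple[str, str]]]:
    """Weighted PPI edge list, pathway collection and the planted pair ids.

    The PPI degree sequence is approximately power-law (Chung-Lu expected
    degrees with the configured exponent, scaled to the configured mean
    degree); confidences are uniform integers in [150, 1000].  For each
    planted crosstalk pair, ``crosstalk_excess_edges`` extra high-confidence
    edges are added between exclusive members of the two pathways.
    """
    rng = config.stage_rng("ppi")
    genes = config.gene_ids()
    n = len(genes)
    w = np.power(np.arange(1, n + 1, dtype=float), -1.0 / (config.ppi_degree_exponent - 1.0))
    w *= config.ppi_mean_degree * n / w.sum()
    w = np.minimum(w, np.sqrt(w.sum()))  # keep edge probabilities valid
    g = nx.expected_degree_graph(w, seed=int(rng.integers(2**31)), selfloops=False)
    perm = rng.permutation(n)  # detach degree rank from gene-id order
    edge_rows = []
    for u, v in g.edges():
        a, b = genes[perm[u]], genes[perm[v]]
        edge_rows.append((a, b, int(rng.integers(150, 1001))))

    lo, hi = config.pathway_size_range
    pathways: dict[str, set[str]] = {}
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, n), replace=False)
        pathways[f"PW{i + 1:03d}"] = set(members)

    existing = {(min(a, b), max(a, b)) for a, b, _ in edge_rows}
    planted_pairs = []
    for i in range(config.planted_crosstalk_pairs):
        ia, ib = 2 * i, 2 * i + 1
        if ib >= config.n_pathways:
            raise ConfigurationError("not enough pathways for the planted pairs")
        pa, pb = f"PW{ia + 1:03d}", f"PW{ib + 1:03d}"
        a_only = sorted(pathways[pa] - pathways[pb])
        b_only = sorted(pathways[pb] - pathways[pa])
        added = 0
        attempts = 0
        while added < config.crosstalk_excess_edges and attempts < 10000:
            attempts += 1
            a = a_only[rng.integers(len(a_only))]
            b = b_only[rng.integers(len(b_only))]
            key = (min(a, b), max(a, b))
            if key in existing:
                continue
            existing.add(key)
            edge_rows.append((a, b, int(rng.integers(800, 1001))))
            added += 1
        planted_pairs.append((pa, pb))

    ppi = pd.DataFrame(edge_rows, columns=["node_a", "node_b", "confidence"])
    return ppi, pathways, planted_pairs


def generate_precursor_reads(config: SyntheticConfig) -> dict:
    """Precursor intervals plus per-condition read alignments.

    Precursors are ~100 bp intervals on ``chr1`` named after the miRNA ids;
    the first ``n_planted_demirs`` are differential (alternating up/down by
    ``demir_fold``) in the case condition.  Background reads on ``chr2``
    contribute to library size only.  Returns a dict with ``precursors``,
    per-condition ``reads`` DataFrames (BED6 columns) and ``library_sizes``.
    """
    rng = config.stage_rng("reads")
    mirs = config.mirna_ids()
    rows = []
    pos = 10_000
    for m in mirs:
        length = int(rng.integers(80, 121))
        rows.append(("chr1", pos, pos + length, m, "0", "+"))
        pos += length + int(rng.integers(200, 1000))
    precursors = pd.DataFrame(rows, columns=BED6_COLUMNS)

    base_rate = np.exp(rng.normal(np.log(config.reads_mean_per_precursor), 0.6, len(mirs)))
    fold = np.ones(len(mirs))
    planted_status = {}
    for i in range(min(config.n_planted_demirs, len(mirs))):
        if i % 2 == 0:
            fold[i] = config.demir_fold
            planted_status[mirs[i]] = "up"
        else:
            fold[i] = 1.0 / config.demir_fold
            planted_status[mirs[i]] = "down"

    reads = {}
    library_sizes = {}
    for condition, rates in (("IPF", base_rate * fold), ("control", base_rate)):
        rrows = []
        for (_, pre), rate in zip(precursors.iterrows(), rates):
            n_reads = rng.poisson(rate)
            span = pre.end - pre.start
            starts = pre.start + rng.integers(0, max(span - 36, 1), size=n_reads)
            for j, st in enumerate(starts):
                rrows.append(("chr1", int(st), int(st) + 36,
                              f"{condition}_read_{pre['name']}_{j}", "0", "+"))
        bg_starts = rng.integers(0, 5_000_000, size=config.n_background_reads)
        for j, st in enumerate(bg_starts):
            rrows.append(("chr2", int(st), int(st) + 36, f"{condition}_bg_{j}", "0", "+"))
        df = pd.DataFrame(rrows, columns=BED6_COLUMNS)
        reads[condition] = df
        library_sizes[condition] = len(df)

    return {
        "precursors": precursors,
        "reads": reads,
        "library_sizes": library_sizes,
        "planted_status": planted_status,
    }


def generate_mirna_microarray_records(
    config: SyntheticConfig,
    n_studies: int = 2,
    agreement: float = 0.95,
) -> pd.DataFrame:
    """Microarray-style DEmiR status tables supporting the planted set.

    Each emulated study reports the planted status with probability
    ``agreement`` (flipped otherwise) and ``unchanged`` for the rest, giving
    the consensus stage genuinely multi-study input.
    """
    rng = config.stage_rng("mirna_ma")
    planted = {}
    for i in range(min(config.n_planted_demirs, config.n_mirnas)):
        planted[config.mirna_ids()[i]] = "up" if i % 2 == 0 else "down"
    rows = []
    for s in range(n_studies):
        sid = f"mirna_ma{s + 1}"
        for m in config.mirna_ids():
            status = planted.get(m, "unchanged")
            if status != "unchanged" and rng.random() > agreement:
                status = "down" if status == "up" else "up"
            rows.append({
                "mirna": m, "rpkm_case": np.nan, "rpkm_control": np.nan,
                "log2fc": np.nan, "status": status,
                "source": "microarray", "study_id": sid,
            })
    return pd.DataFrame(rows)
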