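"""End-to-end orchestration: expression -> consensus -> miRNA -> classification
-> regulatory network/motifs -> pathway crosstalk.

Stages run in dependency order from a single declarative configuration, each
writing its intermediate tables as TSV under the output directory, plus a
run manifest (seeds, thresholds, package versions) and a summary report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, crosstalk, expression, mirna, network
from ._errors import ConfigurationError
from .datatypes import ExpressionStudy
from .io import write_bed6, write_expression_tsv, write_gmt, write_labels_tsv, \
    write_ppi_tsv, write_regulatory_tsv
from .synthetic import SyntheticConfig, generate_expression_studies, \
    generate_mirna_microarray_records, generate_ppi_and_pathways, \
    generate_precursor_reads, generate_regulatory_tables, node_classes_for

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, stage toggles and the master seed of one run.

    The threshold defaults are the reference operating point of the
    analysis: |log2FC| >= 1 and alpha 0.05 for differential calls, target
    anti-correlation r <= -0.7, >= 2 supporting studies for consensus,
    clique percolation k = 3, 1000 randomizations, >= 6 genes per pathway,
    PPI confidence >= 500 for neighborhoods, 5-fold cross-validation with
    10 repeats.
    """

    seed: int = 0
    outdir: str = "fibrosysmap_run"
    log2fc_min: float = 1.0
    alpha: float = 0.05
    r_max: float = -0.7
    min_studies: int = 2
    k_clique: int = 3
    n_random: int = 1000
    swap_multiplier: int = 10
    min_genes: int = 6
    min_confidence: int = 500
    folds: int = 5
    repeats: int = 10
    stages: dict[str, bool] = field(default_factory=lambda: {
        "expression": True, "mirna": True, "classification": True,
        "network": True, "crosstalk": True,
    })
    synthetic: SyntheticConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = SyntheticConfig(**synth)
        return cfg


def _write_manifest(cfg: PipelineConfig, outdir: Path, timings: dict[str, float]) -> None:
    import networkx, numpy, pandas, sklearn  # noqa: PLC0415

    manifest = {
        "config": {k: v for k, v in asdict(cfg).items() if k != "synthetic"},
        "synthetic": asdict(cfg.synthetic) if cfg.synthetic else None,
        "versions": {
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "stage_wall_times_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages on a synthetic cohort; returns the summary.

    Aborts with the stage name on any stage failure.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synth = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
    summary: dict = {"seed": cfg.seed}
    timings: dict[str, float] = {}
    stage = "synthetic_data"
    try:
        t0 = time.perf_counter()
        studies = generate_expression_studies(synth)
        reg_edges, profiles = generate_regulatory_tables(synth, studies)
        ppi_df, pathways, planted_pairs = generate_ppi_and_pathways(synth)
        reads_bundle = generate_precursor_reads(synth)
        inputs = outdir / "inputs"
        inputs.mkdir(exist_ok=True)
        for st in studies:
            write_expression_tsv(st.matrix, inputs / f"{st.study_id}_matrix.tsv")
            write_labels_tsv(st.sample_labels, inputs / f"{st.study_id}_labels.tsv")
        write_regulatory_tsv(reg_edges, inputs / "regulatory_edges.tsv")
        write_ppi_tsv(ppi_df, inputs / "ppi.tsv")
        write_gmt(pathways, inputs / "pathways.gmt")
        write_bed6(reads_bundle["precursors"], inputs / "precursors.bed")
        timings[stage] = time.perf_counter() - t0

        deg_tables: list[pd.DataFrame] = []
        set_b = None
        if cfg.stages.get("expression", True):
            stage = "expression"
            t0 = time.perf_counter()
            deg_tables = [
                expression.call_degs(st, log2fc_min=cfg.log2fc_min, alpha=cfg.alpha)
                for st in studies
            ]
            for tbl in deg_tables:
                sid = tbl["study_id"].iat[0] if len(tbl) else "empty"
                tbl.to_csv(outdir / f"degs_{sid}.tsv", sep="\t", index=False)
            rnaseq_tables = [t for st, t in zip(studies, deg_tables)
                             if st.platform == "rnaseq"]
            set_a = expression.intersect_deg_sets(
                rnaseq_tables[:2] if len(rnaseq_tables) >= 2 else deg_tables[:2],
                name="A")
            set_b = expression.build_pairwise_consensus(
                deg_tables, min_studies=cfg.min_studies, name="B")
            expression.consensus_to_tsv(set_a, outdir / "consensus_set_A.tsv")
            expression.consensus_to_tsv(set_b, outdir / "consensus_set_B.tsv")
            summary["set_a_size"] = len(set_a)
            summary["set_b_size"] = len(set_b)
            planted = synth.planted_degs()
            covered_2plus = {
                g for g in planted
                if sum(g in st.genes for st in studies) >= cfg.min_studies
            }
            recovered = covered_2plus & set_b.genes()
            summary["planted_deg_recovery_pct"] = round(
                100.0 * len(recovered) / len(covered_2plus), 2) if covered_2plus else None
            timings[stage] = time.perf_counter() - t0

        if cfg.stages.get("mirna", True):
            stage = "mirna"
            t0 = time.perf_counter()
            pre = reads_bundle["precursors"]
            lengths = pd.Series((pre["end"] - pre["start"]).to_numpy(),
                                index=pre["name"].to_numpy())
            counts = {
                cond: mirna.count_precursor_overlaps(reads_bundle["reads"][cond], pre)
                for cond in ("IPF", "control")
            }
            proxy = mirna.proxy_demir_call(
                counts["IPF"], counts["control"], lengths,
                reads_bundle["library_sizes"]["IPF"],
                reads_bundle["library_sizes"]["control"],
                log2fc_min=cfg.log2fc_min)
            ma_records = generate_mirna_microarray_records(synth)
            demirs = mirna.consensus_demir(
                pd.concat([proxy, ma_records], ignore_index=True),
                min_studies=cfg.min_studies)
            proxy.to_csv(outdir / "mirna_proxy_calls.tsv", sep="\t", index=False)
            demirs.to_csv(outdir / "demir_consensus.tsv", sep="\t", index=False)
            candidates = reg_edges[reg_edges["edge_type"] == "miRNA->gene"].rename(
                columns={"source": "mirna", "target": "gene"})[["mirna", "gene"]]
            filtered_targets = mirna.filter_targets_by_anticorrelation(
                candidates, profiles, r_max=cfg.r_max)
            filtered_targets.to_csv(outdir / "mirna_targets_filtered.tsv",
                                    sep="\t", index=False)
            summary["demir_consensus_size"] = len(demirs)
            planted_status = reads_bundle["planted_status"]
            hits = sum(
                1 for m, s in planted_status.items()
                if ((demirs["mirna"] == m) & (demirs["status"] == s)).any())
            summary["planted_demir_recovery_pct"] = round(
                100.0 * hits / len(planted_status), 2) if planted_status else None
            summary["anticorrelated_target_pairs"] = len(filtered_targets)
            timings[stage] = time.perf_counter() - t0

        if cfg.stages.get("classification", True):
            stage = "classification"
            t0 = time.perf_counter()
            ma_studies = [s for s in studies if s.platform == "microarray"]
            target = ma_studies[0] if ma_studies else studies[0]
            features = sorted(set_b.genes() & set(target.genes)) if set_b else None
            z = classify.zscore_transform(target.matrix)
            km = classify.kmeans_evaluate(z, target.sample_labels, features=features,
                                          seed=cfg.seed, study_id=target.study_id)
            cv = classify.crossval_classify(z, target.sample_labels, features=features,
                                            folds=cfg.folds, repeats=cfg.repeats,
                                            seed=cfg.seed, study_id=target.study_id)
            cv.to_csv(outdir / "crossval_metrics.tsv", sep="\t")
            summary["kmeans_success_rate_pct"] = km.success_rate_pct
            summary["kmeans_misclassified"] = km.n_misclassified
            summary["cv_mean_accuracy"] = round(float(cv.loc["mean", "accuracy"]), 4)
            summary["cv_mean_mcc"] = round(float(cv.loc["mean", "mcc"]), 4)
            summary["cv_mean_auc"] = round(float(cv.loc["mean", "auc"]), 4)
            timings[stage] = time.perf_counter() - t0

        if cfg.stages.get("network", True):
            stage = "network"
            t0 = time.perf_counter()
            net = network.assemble_grn(reg_edges, node_classes_for(synth))
            metrics = network.network_metrics(net)
            metrics.to_csv(outdir / "network_metrics.tsv", sep="\t")
            hubs = network.identify_hubs(net)
            motifs = network.enumerate_ffls(net)
            null_cfg = network.NullModelConfig(
                n_random=cfg.n_random, swap_multiplier=cfg.swap_multiplier,
                alpha=cfg.alpha, seed=cfg.seed)
            annotated, retained = network.ffl_significance(net, motifs, null_cfg)
            network.motifs_to_frame(annotated).to_csv(
                outdir / "ffl_motifs.tsv", sep="\t", index=False)
            modules = network.clique_percolation(net, k=cfg.k_clique)
            with open(outdir / "modules.tsv", "w") as fh:
                for i, mod in enumerate(modules):
                    fh.write(f"module{i + 1}\t{';'.join(sorted(mod))}\n")
            net_summary = network.summarize_network(net)
            summary["network"] = net_summary
            summary["hubs"] = hubs
            summary["ffl_counts"] = {
                c: sum(m.motif_class == c for m in motifs)
                for c in ("TF-FFL", "miRNA-FFL", "composite-4")
            }
            summary["ffl_significant"] = len(retained)
            summary["cpm_modules"] = len(modules)
            timings[stage] = time.perf_counter() - t0

        if cfg.stages.get("crosstalk", True):
            stage = "crosstalk"
            t0 = time.perf_counter()
            ppi = crosstalk.PPINetwork(ppi_df)
            filtered = crosstalk.filter_pathways(pathways, min_genes=cfg.min_genes)
            results = crosstalk.crosstalk_significance(
                filtered, ppi, n_random=cfg.n_random, seed=cfg.seed)
            directions = set_b.members if set_b else {}
            crosstalk.filter_up_up_pairs(results, filtered, directions)
            crosstalk.results_to_frame(results).to_csv(
                outdir / "crosstalk.tsv", sep="\t", index=False)
            sig = [r for r in results if r.p_empirical <= cfg.alpha]
            summary["crosstalk_pairs_tested"] = len(results)
            summary["crosstalk_significant"] = len(sig)
            planted_p = {
                f"{a}~{b}": r.p_empirical
                for a, b in planted_pairs for r in results
                if {r.pathway_a, r.pathway_b} == {a, b}
            }
            summary["planted_crosstalk_p"] = planted_p
            up_genes = {g for g, d in directions.items() if d == "up"}
            neighborhood = crosstalk.extract_neighborhood(
                up_genes & set(ppi.adj), ppi, min_confidence=cfg.min_confidence)
            enr = crosstalk.enrich_partitioned(
                neighborhood, directions, pathways,
                universe=set(synth.gene_ids()), alpha=cfg.alpha)
            for part, table in enr.items():
                table.to_csv(outdir / f"enrichment_{part}.tsv", sep="\t", index=False)
            summary["neighborhood_size"] = len(neighborhood)
            timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_manifest(cfg, outdir, timings)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def run_demo(seed: int, outdir: str, n_random: int = 1000) -> dict:
    """One-command synthetic end-to-end demo at the reference conditions."""
    cfg = PipelineConfig(seed=seed, outdir=outdir, n_random=n_random,
                         synthetic=SyntheticConfig(seed=seed))
    return run_pipeline(cfg)
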