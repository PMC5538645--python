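"""End-to-end driver: simulate -> contrasts -> consensus -> ordination ->
network -> communities -> enrichment -> regulatory -> UTR scan, with a run
manifest recording every threshold applied and a digest of every output.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, enrichment, motif_scan, network, ordination, regulatory
from .io_formats import write_network
from .synthetic_data import (
    CONTRASTS,
    SIGN_CONVENTIONS,
    SimConfig,
    generate_study,
    write_study,
)


@dataclass
class RunConfig:
    seed: int
    n_mrna: int = 2000
    n_lnc: int = 150
    replicates: int = 3
    de_alpha: float = 0.05
    de_min_abs_log2fc: float = 1.0
    consensus_k_network: int = 3
    consensus_k_list: int = 4
    network_fdr: float = 0.05
    min_fpkm_pca: float = 5.0
    lnc_annotation_alpha: float = 0.01
    gsea_n_perm: int = 200
    gsea_weight: float = 1.0
    tissue_ratio: float = 5.0
    tissue_min_fpkm: float = 1.0
    bat_selective_fold: float = 3.0
    promoter_window: int = 50_000
    scan_window: int = 100
    scan_tier: int = 20

    def validate(self) -> None:
        if self.consensus_k_network > 5 or self.consensus_k_list > 5:
            raise ValueError(
                "consensus k_min cannot exceed the 5 available contrasts"
            )
        if not 0 < self.network_fdr < 1:
            raise ValueError("network_fdr must be in (0,1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(log_lines: list[str], msg: str) -> None:
    log_lines.append(msg)


def run_all(config: RunConfig, outdir) -> RunManifest:
    """Run the full synthetic-mode pipeline; any stage failure quarantines
    partial outputs under ``outdir/failed`` and re-raises naming the stage."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), seed=config.seed)
    log_lines: list[str] = []
    stage = "init"
    try:
        # ------------------------------------------------------------- simulate
        stage = "simulate"
        sim = SimConfig(seed=config.seed, n_mrna=config.n_mrna,
                        n_lnc=config.n_lnc, replicates=config.replicates)
        study = generate_study(sim)
        write_study(study, outdir / "simulated")
        truth = study["truth"]
        expr = study["expression"]
        manifest.stages.append(stage)
        _log(log_lines, f"simulate: {len(truth.gene_ids)} genes, "
                        f"{len(expr.sample_ids)} samples, seed={config.seed}")

        # ------------------------------------------------------------ contrasts
        stage = "contrasts"
        results = {}
        for name, depot, treat, _sign in CONTRASTS:
            df = differential.compute_contrast(
                expr, (depot, treat), (depot, "control"), contrast=name,
                alpha=config.de_alpha,
                min_abs_log2fc=config.de_min_abs_log2fc,
            )
            df.to_csv(outdir / f"contrast_{name}.tsv", sep="\t", index=False)
            results[name] = df
            _log(log_lines,
                 f"contrast {name}: thresholds FDR<={config.de_alpha}, "
                 f"|log2FC|>={config.de_min_abs_log2fc}")
        manifest.stages.append(stage)

        # ------------------------------------------------------------ consensus
        stage = "consensus"
        cons_net = differential.consensus_filter(
            results, k_min=config.consensus_k_network, mode="any",
            sign_conventions=SIGN_CONVENTIONS, alpha=config.de_alpha,
            min_abs_log2fc=config.de_min_abs_log2fc,
        )
        cons_list = differential.consensus_filter(
            results, k_min=config.consensus_k_list, mode="concordant",
            sign_conventions=SIGN_CONVENTIONS, alpha=config.de_alpha,
            min_abs_log2fc=config.de_min_abs_log2fc,
        )
        cons_net.table.to_csv(outdir / "consensus_network_input.tsv",
                              sep="\t", index=False)
        cons_list.table.to_csv(outdir / "consensus_concordant.tsv",
                               sep="\t", index=False)
        manifest.stages.append(stage)
        _log(log_lines,
             f"consensus: {len(cons_net.table)} genes at k>={cons_net.k_min} "
             f"(any), {len(cons_list.table)} at k>={cons_list.k_min} "
             "(concordant)")

        # ----------------------------------------------------------- ordination
        stage = "ordination"
        filtered = ordination.filter_expressed(expr, config.min_fpkm_pca)
        pca = ordination.pca_samples(filtered)
        pca.scores.iloc[:, :5].to_csv(outdir / "pca_scores.tsv", sep="\t",
                                      index_label="sample_id")
        pd.DataFrame(
            {"component": [f"PC{i+1}" for i in
                           range(len(pca.variance_fractions))],
             "variance_fraction": pca.variance_fractions}
        ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
        z, leaves = ordination.hcluster_samples(filtered)
        pd.DataFrame(z, columns=["left", "right", "height", "size"]).to_csv(
            outdir / "hcluster_linkage.tsv", sep="\t", index=False
        )
        manifest.stages.append(stage)
        _log(log_lines,
             f"ordination: FPKM>{config.min_fpkm_pca} filter kept "
             f"{len(filtered.gene_ids)} genes; transform=log2(FPKM+1); "
             "ward on 1-spearman")

        # -------------------------------------------------------------- network
        stage = "network"
        net_genes = cons_net.genes()
        if len(net_genes) < 10:
            raise ValueError("too few consensus genes to build a network")
        sub = expr.subset_genes(net_genes)
        x = np.log2(sub.values.to_numpy().T + 1.0)
        shrunk = network.shrink_correlation(x, gene_ids=sub.gene_ids)
        pcor = network.partial_correlation(shrunk.r)
        model = network.fit_edge_null(
            pcor[np.triu_indices(pcor.shape[0], k=1)]
        )
        edges = network.select_edges(
            pcor, model, shrunk.gene_ids, fdr_threshold=config.network_fdr
        )
        graph = network.build_network(edges, truth.biotypes,
                                      nodes=shrunk.gene_ids)
        partition = network.detect_communities(graph)
        write_network(graph, partition, outdir / "network_edges.tsv",
                      outdir / "network_nodes.tsv",
                      outdir / "network.graphml")
        (outdir / "network_null_model.json").write_text(json.dumps(
            {"eta0": model.eta0, "kappa": model.kappa,
             "lambda": shrunk.lam, "n_samples": shrunk.n,
             "fdr_threshold": config.network_fdr,
             "modularity_q": partition.q,
             "n_clusters": len(set(partition.assignment.values()))},
            indent=1, sort_keys=True))
        manifest.stages.append(stage)
        _log(log_lines,
             f"network: {len(net_genes)} genes, lambda={shrunk.lam:.4f}, "
             f"eta0={model.eta0:.4f}, kappa={model.kappa:.2f}, "
             f"{len(edges)} edges at FDR<{config.network_fdr}, "
             f"Q={partition.q:.4f}")

        # ----------------------------------------------------------- enrichment
        stage = "enrichment"
        collection = study["gene_sets"]
        lnc_table = enrichment.annotate_lncrnas(
            graph, collection, alpha=config.lnc_annotation_alpha
        )
        lnc_table.to_csv(outdir / "lncrna_annotation.tsv", sep="\t",
                         index=False)
        universe_mrna = {
            n for n, d in graph.nodes(data=True) if d.get("biotype") == "mRNA"
        }
        from .io_formats import GeneSetCollection
        present = GeneSetCollection(
            sets={name: members for name, members in collection
                  if set(members) & universe_mrna},
            descriptions=collection.descriptions,
        )
        dropped_sets = sorted(set(collection.sets) - set(present.sets))
        if dropped_sets:
            _log(log_lines,
                 f"enrichment: {len(dropped_sets)} gene set(s) with no "
                 f"members in the network universe skipped: {dropped_sets}")
        cluster_table = enrichment.cluster_overrep(graph, partition, present)
        cluster_table.to_csv(outdir / "cluster_overrepresentation.tsv",
                             sep="\t", index=False)
        gsea_rows = []
        ranked = results["iWAT_cold"].set_index("gene_id")["log2fc"]
        for set_name, members in collection:
            members_in = set(members) & set(ranked.index)
            if not members_in or members_in == set(ranked.index):
                continue
            res = enrichment.preranked_gsea(
                ranked, members, weight=config.gsea_weight,
                n_perm=config.gsea_n_perm, seed=config.seed,
                name=set_name,
            )
            gsea_rows.append(asdict(res))
        pd.DataFrame(gsea_rows).to_csv(outdir / "gsea_iWAT_cold.tsv",
                                       sep="\t", index=False)
        manifest.stages.append(stage)
        _log(log_lines,
             f"enrichment: lncRNA alpha={config.lnc_annotation_alpha}, "
             f"GSEA n_perm={config.gsea_n_perm} seed={config.seed}")

        # ----------------------------------------------------------- regulatory
        stage = "regulatory"
        panel = study["tissue_panel"]
        tsets = regulatory.tissue_specific_sets(
            panel, ratio=config.tissue_ratio, min_fpkm=config.tissue_min_fpkm
        )
        universe = set(truth.gene_ids)
        up_genes = {
            g for g in cons_list.table.loc[
                cons_list.table["consensus_direction"] == "up", "gene_id"
            ]
        }
        spec_results = regulatory.specificity_overlap(
            up_genes, tsets, universe
        )
        pd.DataFrame([asdict(r) for r in spec_results]).to_csv(
            outdir / "tissue_specificity_overlap.tsv", sep="\t", index=False
        )
        bat_sel = regulatory.bat_selective_genes(
            panel["BAT"], panel["iWAT"], panel["eWAT"],
            fold=config.bat_selective_fold,
        )
        pd.Series(sorted(bat_sel), name="gene_id").to_csv(
            outdir / "bat_selective_genes.tsv", sep="\t", index=False
        )
        windows = regulatory.promoter_windows(
            truth.annotation, width=config.promoter_window
        )
        summary, flags = regulatory.peak_promoter_enrichment(
            list(study["peaks"].values()), windows,
            up_genes, universe,
        )
        summary.to_csv(outdir / "peak_promoter_enrichment.tsv", sep="\t",
                       index=False)
        flags.to_csv(outdir / "peak_promoter_flags.tsv", sep="\t",
                     index_label="gene_id")
        manifest.stages.append(stage)
        _log(log_lines,
             f"regulatory: tissue ratio>={config.tissue_ratio}, "
             f"BAT-selective fold>={config.bat_selective_fold}, "
             f"promoter window={config.promoter_window}")

        # -------------------------------------------------------------- scan
        stage = "scan_utr"
        scan_genes = [g for g in sorted(bat_sel) if g in study["utrs"]]
        if scan_genes:
            ranked_cbs = motif_scan.rank_cbs_candidates(
                study["utrs"], genes=scan_genes,
                window=config.scan_window, tier_threshold=config.scan_tier,
            )
            ranked_cbs.to_csv(outdir / "cbs_candidates.tsv", sep="\t",
                              index=False)
        manifest.stages.append(stage)
        _log(log_lines,
             f"scan: window={config.scan_window}, tier>={config.scan_tier}, "
             f"{len(scan_genes)} BAT-selective genes scanned")

        # ------------------------------------------------------------- manifest
        stage = "manifest"
        manifest.thresholds = {
            "de_alpha": config.de_alpha,
            "de_min_abs_log2fc": config.de_min_abs_log2fc,
            "network_fdr": config.network_fdr,
            "min_fpkm_pca": config.min_fpkm_pca,
            "lnc_annotation_alpha": config.lnc_annotation_alpha,
            "scan_tier": config.scan_tier,
        }
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        for path in sorted(outdir.rglob("*")):
            if path.is_file() and path.name not in ("manifest.json",):
                manifest.digests[str(path.relative_to(outdir))] = _digest(path)
        (outdir / "manifest.json").write_text(manifest.to_json())
        manifest.stages.append(stage)
        return manifest
    except Exception as exc:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for path in list(outdir.iterdir()):
            if path.name != "failed":
                shutil.move(str(path), str(failed / path.name))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
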