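"""End-to-end orchestration: simulate -> dmp -> dmg/dmer -> network ->
concordance -> dependence -> pcscore, driven by one config and one seed.

Every stage writes its outputs plus a JSON manifest recording parameters,
input checksums and the seed, so a rerun with the same config is
byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import dependence as dep
from . import divergence as dv
from . import io_formats as iof
from . import network_hubs as nh
from . import pc_score as pcs
from . import region_analysis as ra
from .synthetic_data import SimulationConfig, simulate_expression, simulate_methylomes, simulate_pathways_and_ppi

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All stage thresholds (defaults are the analysis' stated values) plus
    the simulation config and master seed."""

    seed: int = 0
    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        n_genes=200, n_signal_genes=40, n_pathways=40, pathway_size=25,
        ppi_nodes=200, n_enhancers=40, n_hubs=8))
    dmp_alpha: float = 0.05
    hd_weighted: bool = True
    glm_family: str = "negbinom"
    min_count: int = 8
    region_alpha: float = 0.05
    lfc_cutoff: float = 1.0
    min_overlap_bp: int = 500
    score_threshold_build: float = 0.4
    score_threshold_map: float = 0.7
    map_min_degree: int = 3
    kmeans_k: int = 3
    n_boot: int = 100
    n_perm: int = 999
    n_random: int = 200
    enrich_fdr: float = conc.FDR_CONSIDER_THRESHOLD
    enrich_min_genes: int = 2
    with_expression: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimulationConfig(**self.sim)
        if not (0 < self.dmp_alpha < 1 and 0 < self.region_alpha < 1):
            raise ValueError("alpha thresholds must be in (0, 1)")
        if self.min_overlap_bp < 0 or self.min_count < 0:
            raise ValueError("count thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, inputs: list[Path],
                    outputs: list[Path], seed: int) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": params,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_all(config: PipelineConfig, outdir) -> Path:
    """Run every stage in dependency order; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    # ---- stage: simulate -------------------------------------------------
    sim = config.sim if config.sim.seed == config.seed else \
        SimulationConfig(**{**asdict(config.sim), "seed": config.seed})
    rng = np.random.default_rng(sim.seed)
    data = simulate_methylomes(sim, rng)
    pathways, ppi = simulate_pathways_and_ppi(sim, np.random.default_rng(sim.seed + 2))

    sample_paths = []
    for s in data.samples:
        p = outdir / f"methylome_{s.sample_id}.tsv"
        iof.write_methylation_table(s, p)
        sample_paths.append(p)
    genes_bed = outdir / "genes.bed"
    iof.write_bed(data.genes, genes_bed)
    enh_tsv = outdir / "enhancer_tissue_intervals.tsv"
    data.enhancer_tissue_intervals.to_csv(enh_tsv, sep="\t", index=False)
    gmt_path = outdir / "pathways.gmt"
    iof.write_gmt(pathways, gmt_path)
    ppi_path = outdir / "ppi_edges.tsv"
    iof.write_ppi_table(ppi, ppi_path)
    truth_path = outdir / "truth.csv"
    data.truth.to_csv(truth_path, index=False)
    note(f"simulate: {len(data.samples)} samples, "
         f"{data.samples[0].n_sites} sites each, {len(data.genes)} genes")
    _write_manifest(outdir, "simulate", {"sim": asdict(sim)}, [],
                    sample_paths + [genes_bed, enh_tsv, gmt_path, ppi_path, truth_path],
                    config.seed)

    # ---- stage: dmp ------------------------------------------------------
    reference = [s for s in data.samples if s.group == "reference"]
    others = [s for s in data.samples if s.group != "reference"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dmps = dv.call_dmps(others, reference, alpha=config.dmp_alpha,
                            weighted=config.hd_weighted)
    dmp_path = outdir / "dmps.tsv"
    dmps.sites.to_csv(dmp_path, sep="\t", index=False, float_format="%.8g")
    wig_paths = []
    for group in ("control", "treatment"):
        values = dv.group_mean_level_difference(others, reference, group)
        p = outdir / f"meth_diff_{group}.wig"
        iof.write_wig(f"mean_meth_diff_{group}", values, p)
        wig_paths.append(p)
    note(f"dmp: cutoff={dmps.cutoff:.6g} J={dmps.youden_j:.3f} n_dmps={len(dmps)}")
    _write_manifest(outdir, "dmp",
                    {"alpha": config.dmp_alpha, "weighted": config.hd_weighted,
                     "cutoff": dmps.cutoff},
                    sample_paths, [dmp_path, *wig_paths], config.seed)

    groups = {s.sample_id: s.group for s in others}

    # ---- stage: dmg ------------------------------------------------------
    gene_counts = ra.count_dmps_per_region(dmps.sites, data.genes, groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dmg_res = ra.glm_count_test(gene_counts, family=config.glm_family,
                                    min_count=config.min_count,
                                    alpha=config.region_alpha,
                                    lfc_cutoff=config.lfc_cutoff)
    dmg_csv = outdir / "dmg_results.csv"
    dmg_res.to_csv(dmg_csv, float_format="%.8g")
    dmg_names = list(dmg_res.index[dmg_res["is_dm"]])
    dmg_bed = outdir / "dmgs.bed"
    iof.write_bed(data.genes.subset(dmg_names), dmg_bed)
    note(f"dmg: tested={int(dmg_res['tested'].sum())} dmgs={len(dmg_names)}")
    _write_manifest(outdir, "dmg",
                    {"family": config.glm_family, "min_count": config.min_count,
                     "alpha": config.region_alpha, "lfc": config.lfc_cutoff},
                    [dmp_path, genes_bed], [dmg_csv, dmg_bed], config.seed)

    # ---- stage: dmer -----------------------------------------------------
    enhancers = ra.span_enhancers(data.enhancer_tissue_intervals)
    enh_counts = ra.count_dmps_per_region(dmps.sites, enhancers, groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dmer_res = ra.glm_count_test(enh_counts, family=config.glm_family,
                                     min_count=config.min_count,
                                     alpha=config.region_alpha,
                                     lfc_cutoff=config.lfc_cutoff)
    dmer_csv = outdir / "dmer_results.csv"
    dmer_res.to_csv(dmer_csv, float_format="%.8g")
    dmer_names = list(dmer_res.index[dmer_res["is_dm"]])
    note(f"dmer: tested={int(dmer_res['tested'].sum())} dmers={len(dmer_names)}")

    # ---- expression (synthetic DEG table) --------------------------------
    pooled = dv.pool_reference(reference)
    div_all = pd.concat([dv.divergence_table(s, pooled) for s in others], ignore_index=True)
    hd_sig = ra.signal_matrix(div_all, data.genes, metric="hd")
    gene_density = hd_sig.mean(axis=0)
    expr_path = None
    expression = None
    if config.with_expression:
        expression = simulate_expression(sim, gene_density, np.random.default_rng(sim.seed + 1))
        expr_path = outdir / "expression.tsv"
        iof.write_expression_table(expression, expr_path)

    # DMER vs DEG-DMG overlap (>= min_overlap_bp)
    overlap_csv = outdir / "dmer_deg_dmg_overlap.csv"
    if expression is not None:
        deg_dmg = sorted(set(dmg_names) & expression.degs())
        pairs = ra.overlap_filter(enhancers.subset(dmer_names),
                                  data.genes.subset(deg_dmg),
                                  min_overlap_bp=config.min_overlap_bp)
        pairs.to_csv(overlap_csv, index=False)
        note(f"dmer-overlap: {len(pairs)} pairs at >= {config.min_overlap_bp} bp")
    _write_manifest(outdir, "dmer",
                    {"min_overlap_bp": config.min_overlap_bp},
                    [dmp_path, enh_tsv],
                    [dmer_csv] + ([overlap_csv, expr_path] if expression is not None else []),
                    config.seed)

    # ---- stage: network --------------------------------------------------
    graph = nh.build_graph(ppi, score_threshold=config.score_threshold_build)
    cent = nh.centralities(graph)
    cent_csv = outdir / "centralities.csv"
    cent.to_csv(cent_csv, float_format="%.8g")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hubs = nh.kmeans_hub_clusters(cent, k=config.kmeans_k, seed=config.seed,
                                      n_boot=config.n_boot)
    clusters_csv = outdir / "hub_clusters.csv"
    pd.DataFrame({"node": hubs.labels.index, "cluster": hubs.labels.to_numpy()}).to_csv(
        clusters_csv, index=False)
    note(f"network: {graph.number_of_nodes()} nodes; jaccard="
         + ",".join(f"{j:.3f}" for j in hubs.jaccard))

    background = set(graph.nodes) | pathways.universe()
    enrich_dmg = nh.hypergeom_enrichment(set(dmg_names) & background, pathways,
                                         background, min_genes=config.enrich_min_genes) \
        if dmg_names else pd.DataFrame(columns=["pathway_id", "n_genes_in_set", "pathway_size", "p_value", "fdr_p"])
    enrich_dmg_csv = outdir / "enrichment_dmg.csv"
    enrich_dmg.to_csv(enrich_dmg_csv, index=False, float_format="%.8g")

    # Ward clustering of methylation signal + mapping into the PPI network
    sig_cols = [g for g in hd_sig.columns if hd_sig[g].std() > 0]
    ward_csv = outdir / "ward_clusters.csv"
    if len(sig_cols) >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ward_labels, ward_support = nh.ward_signal_clusters(
                hd_sig[sig_cols].T, n_clusters=config.kmeans_k,
                n_boot=config.n_boot, seed=config.seed)
        pd.DataFrame({"gene": ward_labels.index, "cluster": ward_labels.to_numpy()}).to_csv(
            ward_csv, index=False)
        clusters = {str(c): set(ward_labels.index[ward_labels == c])
                    for c in sorted(ward_labels.unique())}
        mapping = nh.map_clusters_to_network(
            clusters, ppi, score_threshold=config.score_threshold_map,
            min_degree=config.map_min_degree, n_random=config.n_random,
            seed=config.seed)
        mapping_csv = outdir / "cluster_network_mapping.csv"
        pd.DataFrame([
            {"cluster": m.cluster, "fraction": m.fraction, "empirical_p": m.empirical_p}
            for m in mapping
        ]).to_csv(mapping_csv, index=False, float_format="%.8g")
    else:
        mapping_csv = None
        note("network: too few variable genes for ward clustering; skipped")
    _write_manifest(outdir, "network",
                    {"score_threshold": config.score_threshold_build, "k": config.kmeans_k},
                    [ppi_path, gmt_path],
                    [p for p in (cent_csv, clusters_csv, enrich_dmg_csv, ward_csv, mapping_csv)
                     if p is not None and p.exists()],
                    config.seed)

    # ---- stage: concordance ---------------------------------------------
    if expression is None:
        note("concordance: skipped (no expression input)")
    else:
        degs = expression.degs() & background
        enrich_deg = nh.hypergeom_enrichment(degs, pathways, background,
                                             min_genes=config.enrich_min_genes)
        enrich_deg_csv = outdir / "enrichment_deg.csv"
        enrich_deg.to_csv(enrich_deg_csv, index=False, float_format="%.8g")
        scores = conc.pathway_scores(enrich_dmg, enrich_deg,
                                     fdr_threshold=config.enrich_fdr)
        scores_csv = outdir / "pathway_scores.csv"
        scores.to_csv(scores_csv, index=False, float_format="%.8g")
        conc_json = outdir / "concordance.json"
        if len(scores) >= 3 and (scores["p_dmg"].var() > 0 or scores["p_deg"].var() > 0):
            report = conc.concordance_report(scores, n_boot=config.n_boot * 10,
                                             n_perm=config.n_perm, seed=config.seed)
            with open(conc_json, "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            note(f"concordance: ccc={report['ccc']:.3f} W={report['kendall_w']:.3f} "
                 f"on {report['n_pathways']} pathways")
        else:
            note("concordance: too few scored pathways; statistics skipped")
        _write_manifest(outdir, "concordance", {"fdr": config.enrich_fdr},
                        [enrich_dmg_csv, enrich_deg_csv],
                        [p for p in (scores_csv, conc_json) if p.exists()], config.seed)

    # ---- stage: dependence ----------------------------------------------
    if expression is None:
        note("dependence: skipped (no expression input)")
    else:
        merged = pd.DataFrame({
            "gene": gene_density.index,
            "delta_hd_density": gene_density.to_numpy(),
        }).merge(expression.rows[["gene", "log2fc", "deg_flag"]], on="gene")
        merged["abs_log2fc"] = merged["log2fc"].abs()
        dep_json = outdir / "dependence.json"
        x = merged["delta_hd_density"].to_numpy()
        y = merged["abs_log2fc"].to_numpy()
        rho, rho_p = dep.spearman_rho(x, y)
        fit = dep.fgm_fit(dep.pseudo_observations(x), dep.pseudo_observations(y))
        with open(dep_json, "w") as fh:
            json.dump({
                "spearman_rho": rho, "spearman_p": rho_p,
                "fgm_theta": fit.theta, "fgm_loglik": fit.loglik,
                "tau_implied": fit.tau_implied, "rho_s_implied": fit.rho_s_implied,
                "n": fit.n,
            }, fh, indent=2, sort_keys=True)
        xs, ys, z = dep.kde2d(x, y, gridsize=50)
        kde_csv = outdir / "kde2d.csv"
        pd.DataFrame(z, index=np.round(ys, 8), columns=np.round(xs, 8)).to_csv(
            kde_csv, float_format="%.8g")
        note(f"dependence: rho={rho:.3f} theta={fit.theta:.3f}")
        _write_manifest(outdir, "dependence", {}, [expr_path],
                        [dep_json, kde_csv], config.seed)

    # ---- stage: pcscore --------------------------------------------------
    target_genes = [g for g in hd_sig.columns if hd_sig[g].std() > 0]
    if expression is not None:
        deg_dmg = set(dmg_names) & expression.degs()
        if len(deg_dmg) >= 2:
            target_genes = [g for g in target_genes if g in deg_dmg]
    pc_csv = outdir / "pc_scores.csv"
    if len(target_genes) >= 2:
        pca = pcs.pca_signal(hd_sig[target_genes])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept, _frac = pcs.retain_components(pca.eigenvalues)
        dens = ra.region_densities(div_all, data.genes.subset(target_genes), metric="hd")
        table = pcs.gene_pc_scores(pca.loadings["PC1"], dens["delta_density"])
        table.to_csv(pc_csv, float_format="%.8g")
        note(f"pcscore: {len(target_genes)} genes, PC1 fraction="
             f"{pca.variance_fraction[0]:.3f}, kept={kept}")
        _write_manifest(outdir, "pcscore", {"n_genes": len(target_genes)},
                        [dmp_path], [pc_csv], config.seed)
    else:
        note("pcscore: fewer than 2 scoreable genes; skipped")

    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    config.to_yaml(outdir / "config_used.yaml")
    return outdir
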