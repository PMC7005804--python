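"""Seeded synthetic datasets with the statistical structure the analysis assumes.

The generator plants ground truth at every level so downstream stages can be
validated end-to-end:

- per-site baseline methylation drawn from a Beta distribution, shared across
  individuals, with small per-individual noise (natural variability);
- hyper-/hypomethylation shifts planted in designated signal genes of the
  treatment (patient) group;
- negative-binomial read coverage;
- expression fold changes coupled to per-gene methylation density through an
  FGM copula;
- a preferential-attachment PPI graph with designated hubs and a toy pathway
  database mixing hub neighborhoods (signal) and random gene sets (null).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionTable, MethylomeSample, PathwayDB, PPIEdgeTable, RegionSet

__all__ = [
    "SimulationConfig",
    "SyntheticMethylomes",
    "fgm_sample",
    "simulate_methylomes",
    "simulate_expression",
    "simulate_pathways_and_ppi",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data generator; one seed drives everything."""

    n_reference: int = 4
    n_control: int = 4
    n_patient: int = 3
    n_genes: int = 60
    n_enhancers: int = 20
    sites_per_region: int = 30
    baseline_beta: tuple[float, float] = (2.0, 6.0)
    coverage_nb: tuple[float, float] = (30.0, 10.0)  # (mean, dispersion/size)
    n_signal_genes: int = 10
    effect_size: float = 0.4
    hypo_fraction: float = 0.2
    noise_sd: float = 0.03
    copula_theta: float = 0.9
    ppi_nodes: int = 60
    ppi_attachment: int = 2
    n_hubs: int = 5
    n_pathways: int = 25
    pathway_size: int = 12
    gene_length: int = 3000
    gene_gap: int = 1000
    seed: int = 0
    signal_genes: dict[str, float] | None = None

    def __post_init__(self) -> None:
        # YAML round-trips deliver lists; normalize to tuples for equality
        object.__setattr__(self, "baseline_beta", tuple(self.baseline_beta))
        object.__setattr__(self, "coverage_nb", tuple(self.coverage_nb))
        for name in ("n_reference", "n_control", "n_patient"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in ("n_genes", "n_enhancers", "sites_per_region"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.copula_theta) > 1:
            raise ValueError("|copula_theta| must be <= 1")
        if not (0 < self.effect_size <= 1):
            raise ValueError("effect_size must be in (0, 1]")

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def resolved_signal_genes(self) -> dict[str, float]:
        """Per-gene planted effect sizes (defaults: first n_signal_genes at effect_size)."""
        if self.signal_genes is not None:
            return dict(self.signal_genes)
        return {g: self.effect_size for g in self.gene_names()[: self.n_signal_genes]}


@dataclass
class SyntheticMethylomes:
    samples: list[MethylomeSample]
    truth: pd.DataFrame  # gene, is_signal, delta, direction
    genes: RegionSet
    enhancers: RegionSet
    enhancer_tissue_intervals: pd.DataFrame  # name, chrom, start, end (per tissue)


def fgm_sample(n: int, theta: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw n pairs from the FGM copula by the conditional-inverse method.

    Given U=u, the conditional CDF of V is F(v|u) = (1+a)v - a*v**2 with
    a = theta*(1-2u); its inverse is the smaller quadratic root.
    """
    if abs(theta) > 1:
        raise ValueError("|theta| must be <= 1 for the FGM copula")
    u = rng.uniform(size=n)
    w = rng.uniform(size=n)
    a = theta * (1.0 - 2.0 * u)
    v = np.empty(n)
    small = np.abs(a) < 1e-12
    v[small] = w[small]
    anz = a[~small]
    b = 1.0 + anz
    v[~small] = (b - np.sqrt(b * b - 4.0 * anz * w[~small])) / (2.0 * anz)
    return u, np.clip(v, 0.0, 1.0)


def _gene_regions(config: SimulationConfig) -> RegionSet:
    span = config.gene_length + config.gene_gap
    rows = [
        ("chr1", i * span, i * span + config.gene_length, name, "+", "gene")
        for i, name in enumerate(config.gene_names())
    ]
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand", "kind"]))


def _enhancer_intervals(config: SimulationConfig, rng: np.random.Generator,
                        genes: RegionSet) -> tuple[RegionSet, pd.DataFrame]:
    """Per-tissue enhancer intervals plus their spanned regions.

    Each enhancer is anchored near a gene (some overlap the gene body by well
    over 500 bp so the DMER/DMG overlap filter has positives to find).
    """
    gdf = genes.regions
    rows = []
    for i in range(config.n_enhancers):
        gene_row = gdf.iloc[i % len(gdf)]
        anchor = int(gene_row["start"]) + int(rng.integers(-500, config.gene_length // 2))
        anchor = max(anchor, 0)
        n_tissues = int(rng.integers(1, 4))
        for _ in range(n_tissues):
            start = anchor + int(rng.integers(-200, 200))
            start = max(start, 0)
            length = int(rng.integers(600, 1500))
            rows.append((f"E{i:04d}", "chr1", start, start + length))
    tissue = pd.DataFrame(rows, columns=["name", "chrom", "start", "end"])
    spans = tissue.groupby("name").agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
    spans = spans.reset_index()
    spans["strand"] = "."
    spans["kind"] = "enhancer"
    enhancers = RegionSet(spans[["chrom", "start", "end", "name", "strand", "kind"]])
    return enhancers, tissue


def simulate_methylomes(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> SyntheticMethylomes:
    """Generate methylome samples for reference/control/patient groups.

    Latent per-site baseline p ~ Beta(a, b) shared across individuals;
    individual methylation ~ Binomial(n_total, clip(p + noise [+ delta])),
    coverage ~ NB(mean, dispersion) + 1.  Patient samples are shifted by
    +delta (hyper) or -delta (hypo) at sites inside signal genes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_regions(config)
    enhancers, tissue = _enhancer_intervals(config, rng, genes)

    gdf = genes.regions
    site_chrom: list[str] = []
    site_pos: list[int] = []
    site_gene: list[str] = []
    for row in gdf.itertuples(index=False):
        pos = np.sort(rng.choice(np.arange(row.start, row.end), size=config.sites_per_region, replace=False))
        site_chrom.extend([row.chrom] * len(pos))
        site_pos.extend(pos.tolist())
        site_gene.extend([row.name] * len(pos))
    n_sites = len(site_pos)
    pos_arr = np.asarray(site_pos)
    gene_arr = np.asarray(site_gene)

    baseline = rng.beta(config.baseline_beta[0], config.baseline_beta[1], size=n_sites)

    signal = config.resolved_signal_genes()
    sig_names = sorted(signal)
    n_hypo = int(round(config.hypo_fraction * len(sig_names)))
    hypo_set = set(rng.choice(sig_names, size=n_hypo, replace=False)) if n_hypo else set()
    delta_by_site = np.zeros(n_sites)
    for g, d in signal.items():
        mask = gene_arr == g
        delta_by_site[mask] = -d if g in hypo_set else d

    mean_cov, disp = config.coverage_nb
    p_nb = disp / (disp + mean_cov)

    def _draw(sample_id: str, group: str, planted: bool) -> MethylomeSample:
        n_total = rng.negative_binomial(disp, p_nb, size=n_sites) + 1
        p = baseline + rng.normal(0.0, config.noise_sd, size=n_sites)
        if planted:
            p = p + delta_by_site
        p = np.clip(p, 0.0, 1.0)
        n_meth = rng.binomial(n_total, p)
        sites = pd.DataFrame({
            "chrom": site_chrom,
            "pos": pos_arr,
            "strand": "+",
            "context": "CpG",
            "n_meth": n_meth,
            "n_total": n_total,
        })
        return MethylomeSample(sample_id=sample_id, group=group, sites=sites)

    samples = []
    for i in range(config.n_reference):
        samples.append(_draw(f"ref_{i + 1}", "reference", planted=False))
    for i in range(config.n_control):
        samples.append(_draw(f"ctl_{i + 1}", "control", planted=False))
    for i in range(config.n_patient):
        samples.append(_draw(f"pat_{i + 1}", "treatment", planted=True))

    truth = pd.DataFrame({
        "gene": config.gene_names(),
        "is_signal": [g in signal for g in config.gene_names()],
        "delta": [signal.get(g, 0.0) for g in config.gene_names()],
        "direction": [
            ("hypo" if g in hypo_set else "hyper") if g in signal else "none"
            for g in config.gene_names()
        ],
    })
    return SyntheticMethylomes(samples=samples, truth=truth, genes=genes,
                               enhancers=enhancers, enhancer_tissue_intervals=tissue)


def simulate_expression(config: SimulationConfig,
                        methylation_density_per_gene: pd.Series,
                        rng: np.random.Generator | None = None) -> ExpressionTable:
    """Expression fold changes whose ranks follow an FGM copula with the
    per-gene methylation density ranks.

    |log2FC| is the exponential quantile of the copula-coupled uniform; signal
    genes get a DEG flag with probability increasing in their density rank.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    density = methylation_density_per_gene
    n = len(density)
    # couple v to the observed density ranks: draw v | u at u = rank(density)/(n+1)
    order = np.argsort(np.argsort(density.to_numpy(), kind="mergesort"), kind="mergesort")
    u = (order + 1) / (n + 1)
    w = rng.uniform(size=n)
    a = config.copula_theta * (1.0 - 2.0 * u)
    v = np.where(np.abs(a) < 1e-12, w,
                 ((1.0 + a) - np.sqrt((1.0 + a) ** 2 - 4.0 * a * w)) / np.where(np.abs(a) < 1e-12, 1.0, 2.0 * a))
    v = np.clip(v, 1e-12, 1 - 1e-12)
    abs_lfc = -1.5 * np.log(1.0 - v)  # exponential quantile, scale 1.5
    sign = np.where(rng.uniform(size=n) < 0.5, -1.0, 1.0)
    log2fc = sign * abs_lfc

    signal = config.resolved_signal_genes()
    is_signal = density.index.isin(signal)
    p_deg = np.where(is_signal, np.clip(0.2 + 0.8 * u, 0, 1), 0.05)
    deg_flag = rng.uniform(size=n) < p_deg
    p_value = np.where(deg_flag, 10 ** rng.uniform(-8, -3, size=n), rng.uniform(0.05, 1.0, size=n))
    rows = pd.DataFrame({
        "gene": density.index.to_numpy(),
        "log2fc": log2fc,
        "p_value": p_value,
        "deg_flag": deg_flag,
    })
    return ExpressionTable(rows)


def simulate_pathways_and_ppi(config: SimulationConfig,
                              rng: np.random.Generator | None = None
                              ) -> tuple[PathwayDB, PPIEdgeTable]:
    """Scale-free-ish PPI graph (preferential attachment) plus a toy pathway DB.

    Designated hubs are the highest-degree nodes of the generated graph;
    signal pathways are hub neighborhoods, null pathways random gene sets.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = max(config.ppi_nodes, config.n_genes)
    graph = nx.barabasi_albert_graph(n, config.ppi_attachment,
                                     seed=int(rng.integers(0, 2**31 - 1)))
    # map gene names onto nodes so that designated hub names land on the
    # top-degree nodes (ties broken by node id for determinism)
    by_degree = sorted(graph.nodes, key=lambda v: (-graph.degree(v), v))
    names = [f"G{i:04d}" for i in range(n)]
    hub_names = [f"HUB{i:02d}" for i in range(config.n_hubs)]
    mapping: dict[int, str] = {}
    for i, node in enumerate(by_degree):
        if i < config.n_hubs:
            mapping[node] = hub_names[i]
        else:
            mapping[node] = names[i - config.n_hubs]
    graph = nx.relabel_nodes(graph, mapping)

    rows = []
    for a, b in sorted(graph.edges()):
        a, b = min(a, b), max(a, b)
        rows.append((a, b, float(rng.uniform(0.15, 1.0)), float(rng.uniform(0.0, 1.0))))
    edges = PPIEdgeTable(pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score", "coexpression"]))

    all_genes = sorted(graph.nodes)
    signal_genes = sorted(g for g in config.resolved_signal_genes() if g in graph)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    n_signal_pw = max(1, config.n_pathways // 3)
    for i in range(config.n_pathways):
        pid = f"PW{i:03d}"
        if i < n_signal_pw:
            # signal pathway: a hub neighborhood salted with planted signal genes,
            # so methylation- and expression-derived enrichments both hit it
            hub = hub_names[i % len(hub_names)]
            neigh = sorted(graph.neighbors(hub))
            lo = max(2, config.pathway_size // 3)
            hi = min(len(signal_genes), max(lo, int(0.8 * config.pathway_size)))
            n_sig = int(rng.integers(lo, hi + 1)) if hi >= lo and signal_genes else 0
            chosen = set(rng.choice(signal_genes, size=n_sig, replace=False)) if n_sig else set()
            take = min(len(neigh), max(config.pathway_size - 1 - len(chosen), 0))
            if take:
                chosen |= set(rng.choice(neigh, size=take, replace=False))
            chosen.add(hub)
            descriptions[pid] = "hub neighborhood (signal)"
        else:
            chosen = set(rng.choice(all_genes, size=min(config.pathway_size, n), replace=False))
            descriptions[pid] = "random gene set (null)"
        sets[pid] = chosen
    return PathwayDB(sets=sets, descriptions=descriptions), edges
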