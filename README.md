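# methnet

Integrative analysis of differential cytosine methylation (WGBS-style count
data) and differential gene expression, linked through PPI-network hub
detection, pathway-score concordance, copula dependence modeling, and
PCA-based gene scoring.

The pipeline stages:

1. **synthetic_data** — seeded generator for methylomes (Beta baseline +
   planted hyper/hypo signal, negative-binomial coverage), expression fold
   changes coupled to methylation density through an FGM copula, a
   scale-free PPI graph with designated hubs, and a toy pathway database.
2. **divergence** — per-cytosine methylation divergences vs a pooled
   reference group (methylation level, TV, Bayesian-corrected TV, squared
   Hellinger divergence with optional coverage weight), Fisher exact test
   with BH adjustment, and signal-detection DMP classification via the
   Youden-index ROC cutoff (control individuals = negatives, patients =
   positives).
3. **region_analysis** — GLM group comparison of per-region DMP counts
   (Poisson / quasi-Poisson / negative-binomial with LRT, min-count filter,
   BH, |log2FC| > 1) to call DMGs and DMERs; enhancer spanning across
   tissues; ≥ 500-bp overlap filtering; per-kb signal densities.
4. **network_hubs** — PPI graph construction with score threshold and
   iterative min-degree filter; degree / betweenness / closeness /
   clustering / average-shortest-path / stress / radiality centralities;
   K-means hub clustering with bootstrap Jaccard stability (stable at
   ≥ 0.75) and MANOVA (Pillai) validation; hypergeometric pathway
   enrichment; Ward clustering of methylation signal on 1 − corr; cluster →
   network mapping with a random-subset null.
5. **concordance** — pathway scores P = (#genes) × sig with the discretized
   significance scale; Lin's concordance correlation coefficient with
   bootstrap CI; Kendall's W with permutation test; OLS of the
   double-positive scores; Bland–Altman limits; pathway-set overlap.
6. **dependence** — Spearman rank correlation, rank pseudo-observations,
   FGM copula maximum likelihood (implied τ = 2θ/9, ρ_S = θ/3), 2D KDE.
7. **pc_score** — PCA of the individuals × genes signal-density matrix
   (SVD-based), Guttman–Kaiser retention, |PC1 loading| gene ranking.

All genomic coordinates are 0-based half-open internally; WIG output is
1-based per the standard. Every stochastic step takes an explicit seed and
reruns are byte-identical.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py::TestCriterion1SupplementaryConcordance` (four
tests) requires the published supplementary enriched-pathway tables at
`data/supplementary/enriched_pathways_{dmg,deg}.csv` (columns
`pathway_id, n_genes_in_set, fdr_p`); without them those four tests fail
with an explanatory message. Everything else is self-contained.

## CLI

```sh
methnet simulate --seed 1 --outdir fixtures/            # synthetic dataset
methnet dmp --control c1.tsv --treatment p1.tsv \
            --reference r1.tsv --reference r2.tsv --out dmps.tsv
methnet dmg  --dmps dmps.tsv --genes genes.bed \
             --groups '{"c1":"control","p1":"treatment"}' --out dmg.csv
methnet dmer --dmps dmps.tsv --enhancers enhancers.tsv --groups ... --out dmer.csv
methnet network --ppi ppi_edges.tsv --outdir net/
methnet concordance --enrich-dmg enr_dmg.csv --enrich-deg enr_deg.csv --out conc.json
methnet dependence --table merged.tsv --out dep.json
methnet pcscore --matrix signal.csv --densities dens.csv --out scores.csv
methnet run-all --seed 1 --outdir run/                  # full pipeline
```

`run-all` executes every stage on a synthetic dataset (or a YAML config via
`--config`), writing per-stage outputs plus JSON manifests with parameter
values and SHA-256 checksums of all inputs/outputs.

## File formats

- methylation counts: TSV `chrom pos strand context n_meth n_total`
  (optional `## coords=1-based` pragma); a bedGraph (fraction, coverage)
  adapter is provided
- regions: BED3+ (0-based half-open)
- pathways: GMT
- PPI edges: TSV `gene_a gene_b combined_score coexpression`
- expression: TSV `gene log2fc p_value [deg_flag]`
- tracks: variableStep WIG (1-based)
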