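# sctrait

Statistical toolkit for mapping complex-trait GWAS signal onto single-cell
transcriptomes of an immune stimulation time course. It was built for the
setting where dozens of GWAS panels (milk production, health, conformation
traits in dairy cattle) meet a PBMC scRNA-seq experiment sampled before and
after LPS challenge, and one wants to know **which cell types' marker genes
and response genes carry trait signal**, and **how the cells themselves
respond** (proliferation, response-module dynamics).

Four pieces, usable separately or as one pipeline:

1. **Marker-set enrichment with a rotation null.** For a gene set *f* the
   statistic is the sum of squared single-marker effects over the markers
   inside 20-kb windows around the set's genes,
   `T_sum = Σ_{i=1..m_f} b_i²`. Its null comes from cyclical permutation:
   the genome-ordered vector of squared effects is rotated by a random
   offset while gene-set positions stay fixed, preserving LD and the set's
   size/spacing. One-tailed empirical p over 10,000 rotations (enumerated
   exactly whenever the genome has ≤ 10,001 markers), Benjamini–Hochberg
   FDR across the trait × set grid.
2. **Cell-cycle proliferation index.** Per-cell mean expression of a
   G1/S + G2/M gene panel; cells scoring strictly above the across-cluster
   average are "actively proliferating"; the cycle index of a group is its
   proliferating fraction.
3. **Response-module scoring.** Per-module, per-time-point scaled
   expression (z across time points), with a classifier labelling each
   module trajectory *peaked* (rise and return), *sustained* (rise and
   hold) or *flat*.
4. **Pseudocell aggregation.** Averages of 100 cells drawn at random within
   each cluster, the standard stabilisation step before co-expression
   analysis.

A seeded synthetic-data module generates GWAS effect vectors with block
LD and configurable in-set variance inflation, plus negative-binomial count
matrices with known cycling cells and injected module trajectories — so
every stage is testable offline with known ground truth.

## Worked example

```python
import sctrait as st

# --- GWAS enrichment: a genome with one truly enriched gene set ---------
cfg = st.GwasSimConfig(seed=7, enrichment_lambda=3.0)    # 3x effect-SD in-set
base = st.generate_gwas(cfg, trait_id="milk_yield")
enriched = st.GeneSetCatalog({"set00": base.catalog.sets["set00"]})
sim = st.generate_gwas(cfg, enriched, annotation=base.annotation,
                       catalog=base.catalog, trait_id="milk_yield")
grid = st.run_grid([sim.effects], sim.catalog, sim.annotation,
                   window_bp=20_000, n_perm=10_000, seed=7)
```

```
  trait_id set_id  m_f    t_obs  n_exceed  p_emp  q_fdr  exact_flag
milk_yield  set00   80 435.5871         1 0.0008 0.0067        True
milk_yield  set01   78  63.1283      1003 0.8365 0.8641        True
milk_yield  set02   80  85.6112       679 0.5663 0.8641        True
...
```

The enriched set's 80 markers carry T_sum = 435.6 against a null where only
1 of the 1,199 exact rotations exceeds it: p = 2/1199 ≈ 0.0008 (strict
exceedances plus the 1/n floor convention are both visible in the row), and
it is the only set surviving FDR (q = 0.0067 < 0.05). `exact_flag` records
that the null was enumerated, not sampled.

```python
# --- cell states on a synthetic LPS time course -------------------------
sc_cfg = st.ScSimConfig(seed=7, n_cells_per_group=200,
                        cycling_fraction_per_cluster={"monocytes": 0.3})
cycle_panels, module_panels = st.default_panels(sc_cfg.n_genes)
adata = st.normalize(st.generate_sc(sc_cfg, cycle_panels, module_panels).adata)

scores = st.cycle_score(adata, cycle_panels)
flags, tau = st.classify_proliferating(scores, adata.obs["cluster"])
print(st.cycle_index(flags, adata.obs["cluster"]))
# monocytes    0.355     <- true cycling fraction 0.30
# CD4_T        0.094     <- truth 0: the above-average rule pays a small
# B_cells      0.088        false-positive rate in non-cycling clusters

ms = st.module_score(adata, module_panels, group_key="timepoint")
for mod in ms.index:
    print(mod, "->", st.classify_trajectory(ms.loc[mod].to_numpy()))
# core_antiviral -> peaked
# peaked_inflammatory -> peaked
# sustained_inflammatory -> sustained
```

The module table behind those labels (scaled expression per time point)
shows the two shapes the classifier separates: the peaked modules rise from
Control to an interior maximum at 4 h and fall back by 8 h, the sustained
module rises and holds.

## Command line

Every stage is also a subcommand of `sctrait`:

```sh
sctrait simulate-gwas --seed 7 --outdir sim/
sctrait enrich --gwas-dir sim/ --annotation sim/genes.bed \
        --genesets sim/gene_sets.tsv --window 20000 --n-perm 10000 \
        --seed 7 --out grid.tsv
sctrait simulate-sc --seed 7 --outdir sc/
sctrait cellcycle --mtx-dir sc/ --panels sc/panels.tsv --out index.tsv
sctrait module-score --mtx-dir sc/ --panels sc/panels.tsv --out modules.tsv
sctrait pseudocell --mtx-dir sc/ --size 100 --out pseudocells.tsv
sctrait run-all --seed 7 --outdir run/    # full synthetic pipeline + manifest
```

Real data drop in through the same formats: GWAS summary TSV
(`marker, chrom, pos, b`), BED/GFF3 gene annotation, two-column gene-set
and panel TSVs, and an MTX counts bundle with cell metadata.

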