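# phylospat

Grid-based spatial phylogenetics in Python:

- **Metrics** — per-cell taxon richness (TR), weighted endemism (WE),
  phylogenetic diversity (PD), phylogenetic endemism (PE), and the relative
  metrics RPD/RPE against a topology-identical comparison tree with equal
  branch lengths.
- **Null model** — fixed-marginal (fixed-fixed) randomization of the binary
  cells × taxa matrix via curveball trades, with streaming per-cell
  significance estimation for PD, RPD, PE, PE on the comparison tree, and RPE.
- **CANAPE** — two-step classification of cells into neo-, paleo-, mixed,
  and super endemism from the joint randomization.
- **Turnover** — range-weighted phylogenetic turnover between significant
  cells (Sørensen form by default) and deterministic UPGMA clustering.
- **Range modeling** — per-species down-sampling, pooled background
  sampling, penalized logistic suitability on linear + quadratic climate
  features, sensitivity+specificity thresholding, a Gaussian distance-hybrid
  constraint (σ = 50 km default), OTU range unions, and fine-to-coarse
  aggregation with range-expansion diagnostics.
- **Climate summaries** — cross-tabulation of endemism categories and
  turnover clusters against climate variables.
- **Synthetic data** — seeded generators for Yule phylograms/chronograms,
  spatially cohesive ranges with a controllable range-size distribution,
  planted neo/paleo endemism blocks with ground-truth labels, smooth climate
  gradients, and known suitability truth for range-model recovery tests.
- **Pipeline** — orchestration across tree variants and taxon subsets with
  shared seeds, deterministic outputs, and CANAPE agreement tables.

Coordinates are assumed planar and projected (metres); grids use half-open
cells with floor indexing.

## CLI

```sh
# generate a synthetic dataset
phylospat simulate --n-taxa 100 --nx 10 --ny 10 --seed 1 --out dataset/

# per-cell metrics, randomization, CANAPE, turnover, climate crosstab
phylospat metrics   --tree dataset/tree.nwk --matrix dataset/matrix.csv --out metrics.csv
phylospat randomize --tree dataset/tree.nwk --matrix dataset/matrix.csv \
                    --reps 999 --seed 42 --out rand.csv
phylospat canape    --rand rand.csv --out canape.csv
phylospat turnover  --canape canape.csv --matrix dataset/matrix.csv \
                    --tree dataset/tree.nwk --k 5 --out clusters.csv
phylospat climate   --canape canape.csv --climate dataset/climate.csv \
                    --var precip --threshold 500 --out crosstab.csv

# distance-hybrid range models
phylospat sdm-hybrid --occ occ.csv --climate climate.csv --sigma 50000 --out ranges/

# full pipeline from a YAML config
phylospat run --config config.yml
```

File formats: Newick/Nexus trees; occurrence CSV `name,x,y`; OTU map CSV
`binomial,otu`; presence matrices as sparse triplet CSV `cell_id,taxon`
(with the grid in a header comment); per-cell tables as CSV with
`cell_id,x,y` leading columns at full double precision.

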