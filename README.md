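# coactive

Ternary transcriptional-state calling for single-cell RNA-seq and per-cell
coactivation network analysis.

Single-cell expression of a gene is rarely just "on" or "off": across cells
one typically sees a spike of zero counts, a diffuse cloud of low values,
and a heavier mode of genuinely active transcription.  `coactive` classifies
every gene in every cell into one of three states — **0** (no expression,
zero counts), **1** (low expression) or **2** (high/active expression) — by
fitting, per gene, a gamma-normal mixture to the non-zero log2CPM values

    f(x) = (1 − ρ) · Gamma(x; α, β) + ρ · Normal(x; μ, σ²)

with an EM algorithm; a cell is called active when its posterior probability
of the normal component is z ≥ 0.5.  Genes with too few non-zero cells are
rescued by *contextualization*: pooling with randomly selected context genes,
repeated ten times, majority vote with ties resolved downward.

The ternary matrix feeds two analyses aimed at neuronal maturity studies
(olfactory sensory neurons being the motivating system):

* **Maturity-marker scan** — cells are split by the anchor markers OMP
  (mature) and GAP43 (immature) into mutually exclusive groups, and every
  gene is tested for differential activity between groups with Fisher's
  exact test under Bonferroni control (α = 0.01).
* **Per-cell coactivation networks** — each cell's active genes form a
  clique; edges coactive in more than ~1% of all cells are removed, leaving
  the cell's *uniquely* coactive pairs.  Network shape is scored by Freeman
  degree centralization (1 = star/hub topology, 0 = uniformly connected) and
  compared between mature and immature cells with a t-test across a sweep of
  prevalence thresholds.

A synthetic-data module generates count matrices from the same generative
model with planted maturity markers and planted star/clique cell topologies,
with full truth tables, so every stage can be validated end to end.

## Worked example

```sh
coactive simulate --out-dir study --n-genes 500 --n-cells 120 --seed 7
coactive all study/counts.csv --out-dir study/results --seed 11
```

which logs, stage by stage:

```
loaded 500 genes x 120 cells
fitted 500 genes; 0 genes NA
groups: 60 mature, 60 immature, 0 excluded
threshold 0.010: 60 mature vs 60 immature networks, p=0.009316
...
```

`study/results/` then contains `ternary.tsv` (the 0/1/2/NA state matrix),
`mixture_fits.tsv` (per-gene α, β, μ, σ², ρ, convergence), `marker_scan.tsv`
and `centralization_comparison.tsv`.  In `marker_scan.tsv` the 20 genes the
simulation planted as mature-associated (`matA000`…`matA019`) are exactly the
significant rows — e.g.

```
gene     n_active_mature  n_active_immature  odds_ratio  p_bonferroni  direction          significant
matA000  49               8                  28.95       1.08e-11      mature-associated  True
```

meaning the gene is active in 49/60 mature but only 8/60 immature cells, far
beyond what the Bonferroni-corrected Fisher test attributes to chance.  The
centralization comparison is null here (no planted topology): planted star
versus dense-clique topologies are exercised by
`coactive.synthetic.network_study_spec`, under which mature (star) cells
score near 1 and immature (clique) cells near 0 at every threshold in the
0.5–5% sweep.

The same workflow is available as a library — `log2cpm`,
`build_ternary_matrix`, `binarize`, `define_maturity_groups`,
`marker_coactivation_scan`, `edge_prevalence`, `build_cell_network`,
`compare_group_centralization` — see `docs/methods.md` for the model,
estimation details and design choices.

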