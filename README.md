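# drivernet

Driver-gene-anchored network analysis of tumour expression cohorts.

Cancer genomes carry a small set of *driver genes* whose alteration is
causally implicated in the disease. `drivernet` starts from such an
anchor set and asks: which other genes move with the drivers, how are
they wired together at the protein level, which occupy the most central
network positions, and which of those are prognostic? It implements the
four stages of that analysis as a tested, reusable pipeline:

1. **Gene selection by Gaussian mutual information.** For genes *X*, *Y*
   with sample variances C(X), C(Y) and 2×2 joint covariance C(X, Y),

       I(X, Y) = ½ ln[ C(X) · C(Y) / |C(X, Y)| ]   =  −½ ln(1 − r²)

   in nats, with *r* the Pearson correlation. Every candidate gene is
   scored by its maximum MI over the driver set; the descending
   MI-vs-rank curve is fitted with a least-squares polynomial and the
   ranking is cut where the fitted derivative first flattens to a
   threshold α (default −5·10⁻⁴ nats/rank). Drivers ∪ selected genes
   form the *relevant set*. Preprocessing drops genes with more than
   50% missing values and mean-imputes the rest.
2. **PPI network reconstruction** from a STRING-export edge list
   (`protein1`, `protein2`, `combined_score` 0–1000), filtered at a
   confidence cutoff (default 400) and induced on the relevant set.
3. **Node-centrality ranking.** Degree DCᵢ = kᵢ/(N−1); closeness
   CCᵢ = N/Σⱼdᵢⱼ (per-component); betweenness BCᵢ = Σ n{st}ⁱ/g{st} over
   unordered pairs, unnormalized; eigenvector centrality as the unit-norm
   principal eigenvector of the adjacency matrix. The union of the
   per-metric top-*k* lists (k = 10, 20 by default) is the *vital gene*
   set.
4. **Survival screening.** Each vital gene splits samples at its median
   expression; follow-up is censored at 3650 days (ten years) and the
   high/low groups are compared with a two-group log-rank test
   (raw p < 0.05 by default; Benjamini–Hochberg behind a flag).

A bundled synthetic-data generator plants correlated partner genes,
network hubs and a hazard-modifying gene, so every stage has a
parameter-recovery test without any external download.

## Worked example

Run the bundled demo cohort (8 drivers, 3 partners each at ρ = 0.8, 150
noise genes, 300 samples, 5 planted hubs, one hazard gene at hazard
ratio 3):

```sh
drivernet run --demo --seed 1 --outdir demo
```

The selection stage fits a cubic to the MI decay curve (R² = 0.868) and
cuts at rank 72, giving a relevant set of 80 genes (`fit_report.json`,
`relevant_genes.txt`). The centrality stage ranks all 80; the top of
`vital_top10.tsv` is dominated by the planted hubs:

```
gene       in_dc  in_cc  in_bc  in_ec  best_rank  origin
DRV001     True   True   True   True   1          driver
DRV000     True   True   True   True   2          driver
PTN000_01  True   True   True   True   2          selected
DRV002     True   True   True   True   3          driver
PTN000_00  True   True   True   True   4          selected
```

`survival_top10.tsv` screens the 15 vital genes over the 3650-day
horizon and flags the planted hazard gene and its correlated partners:

```
gene       chi2       p          n_high  n_low  significant
DRV000     54.21      1.81e-13   149     151    True
PTN000_01  16.21      5.67e-05   146     154    True
DRV001     0.167      0.682      150     150    False
```

DRV000 is the gene whose high-expression group was simulated with a
threefold hazard, so a log-rank χ² of 54.2 on one degree of freedom is
the expected strong rejection; its partners inherit a diluted effect
through their ρ = 0.8 correlation. Each stage is also available as its
own subcommand (`simulate`, `select`, `network`, `vital`, `survive`)
and as plain library functions.

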