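# hicdyn

Chromatin-architecture dynamics over a differentiation time course.

`hicdyn` reimplements, as a tested and reusable library, the standard
chromatin-organization analyses applied to a multi-stage Hi-C / RNA-seq /
ATAC-seq / 3D-FISH study of cell differentiation:

* **A/B compartments** — per-chromosome PC1 of the observed/expected contact
  correlation matrix at 500 kb, sign-oriented by gene density (A > 0, B < 0);
* **compartment switching** — per-bin one-way ANOVA of replicate PC1 scores
  across time points (p < 0.05) combined with a sign change of the time-point
  means; categories A–B, B–A, A–B–A, B–A–B (four-segment sequences merged into
  A–B / B–A by their first and last sign);
* **compartmentalization strength** — saddle plots (log₂ mean O/E between PC1
  decile pairs) and compartment-stratified distance-decay curves;
* **TAD boundaries** at 40 kb by directionality index,
  DI = sign(B−A)·((A−E)²/E + (B−E)²/E) with E=(A+B)/2, and by insulation
  score (log₂ of a sliding diagonal square over the chromosome mean), with
  boundary sharing at ±80 kb / ±200 kb tolerance and Jaccard indices;
* **trans contacts** — per-locus inter-chromosomal Z-score profiles (top 0.5%
  trimmed), and a gene-set trans-association test against 1000
  chromosome-matched permutations (the trans-interacting-domain statistic),
  plus network edge tables filtered at the median trans count;
* **category enrichment** — genes by peak-expression stage and interval sets
  (e.g. ATAC peaks) against compartment-dynamics categories, normalized by
  the background (gene/peak) density, with chi-squared tests;
* **3D FISH statistics** — diploid filtering (exactly 2 spots per channel),
  volume-normalized distances (X_norm = X_raw · V̄^{1/3} · V^{−1/3}),
  proximity (< 2 µm) and focus-overlap (< 1 µm) calls, and rank-based group
  comparisons (Kruskal–Wallis with Dunn's post-hoc).

Everything runs on a bundled synthetic-data generator (`hicdyn.simulate`)
that plants known compartment labels, switch categories, TAD blocks, trans
hubs, and FISH proximity fractions, so every stage is testable without any
download. Matrices are exchanged as plain-text triplets + bin BED; tracks as
bedGraph; tables as TSV/CSV.

## Worked example

Simulate a 4-time-point × 2-replicate Hi-C time course (4 chromosomes ×
50 bins at 500 kb, 20% of bins planted to switch compartment) and recover the
planted dynamics through the full pipeline (ICE balancing → O/E → PC1 →
ANOVA switch classification):

```python
from hicdyn import simulate, pipeline

cfg = simulate.HiCSimConfig(bins_per_chrom=50, seed=7, switch_fraction=0.2,
                            switch_category_mix=(0.33, 0.49, 0.08, 0.10))
res = pipeline.switch_recovery(cfg)
print(f"planted switching fraction: {res['true_switching_fraction']:.3f}")
print(f"called switching fraction:  {res['called_switching_fraction']:.3f}")
for cat, share in res["called_category_shares"].items():
    print(f"  {cat:6s} called {share:.2f}  (planted {res['true_category_shares'][cat]:.2f})")
```

prints

```
planted switching fraction: 0.200
called switching fraction:  0.179
  A-B    called 0.33  (planted 0.28)
  B-A    called 0.55  (planted 0.60)
  A-B-A  called 0.06  (planted 0.05)
  B-A-B  called 0.06  (planted 0.07)
```

i.e. at this small problem size the pipeline recovers the planted switching
fraction to within ~2 points and the category mix to within a few points each
(the ANOVA filter is conservative, so the called fraction sits slightly below
the planted one).

A command-line interface mirrors the stages:

```bash
hicdyn simulate --seed 1 --out sim/           # matrices + bins + ground truth
hicdyn balance sim/matrix_t0_r1.txt sim/bins.bed --out balanced.txt
hicdyn tads sim/matrix_t0_r1.txt sim/bins.bed --out boundaries.bed
hicdyn run --seed 1 --out demo/               # end-to-end with manifest.json
```

`hicdyn run` writes every output with a SHA-256 checksum manifest; rerunning
with the same seed reproduces all files bit-identically.

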