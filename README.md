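# cats-ards

Whole-blood transcriptomic sub-phenotyping of pediatric acute respiratory
distress syndrome (ARDS), packaged as a tested, reusable pipeline. It is
aimed at critical-care and translational researchers who want to discover
molecular sub-phenotypes in a ventilated cohort and relate them to
clinical outcomes without hand-rolling the statistics each time.

The pipeline covers:

* **Subtype discovery** — k-means clustering of subjects in the full gene
  space of a normalized (log2-like) expression matrix, with the number of
  clusters chosen by the **gap statistic**: for each k,

  ```
  gap(k) = (1/B) Σ_b log W*_kb − log W_k,
  s_k    = sd_b(log W*_kb) · √(1 + 1/B),
  ```

  where `W_k = Σ_r D_r / (2 n_r)` is the pooled within-cluster dispersion
  and the B reference datasets are uniform over each gene's observed
  range. All k whose 95% CI (`gap ± 1.96 s_k`) overlaps that of the
  maximal gap count as statistically similar; after discarding k values
  that leave any cluster with ≤ 10 subjects, the smallest surviving k is
  selected.
* **Characterization** — demographics-table summaries per subtype with
  the Freeman–Halton (r×c) Fisher exact test for categorical variables
  (full enumeration of tables with the observed margins) and
  Kruskal–Wallis tests with rank-based η² effect sizes for continuous
  ones.
* **Outcome models** — PICU mortality via logistic regression (Wald
  inference), and probability of extubation alive by day 28 via
  **Fine–Gray subdistribution-hazard regression** with death as the
  competing risk: subjects with a prior competing event remain in later
  risk sets with inverse-probability-of-censoring weights, Breslow tie
  handling, and a sandwich variance. Kaplan–Meier curves, log-rank tests
  and Aalen–Johansen cumulative incidence are included. Ventilator-free
  days (VFD = 28 − ventilator days; 0 for nonsurvivors or ≥ 28 ventilated
  days), the oxygenation index and the vasopressor score are computed
  from their standard definitions.
* **Gene signatures** — quantile normalization, an expression filter
  (≥ 10 in ≥ 10 samples), one-vs-rest Welch tests per gene, and
  twofold / FDR-q < 0.1 gates.
* **Synthetic cohorts** — a generator planting expression subtypes,
  subtype-linked clinical covariates and competing-risk outcomes, so the
  whole pipeline is testable end to end without any data download.

## Worked example

Simulate a 96-subject cohort with three planted subtypes (sizes 31/29/36,
2,000 genes, 200 informative, +2.0 log2 effect) and run the full
pipeline:

```bash
cat > config.json <<'EOF'
{
  "output_dir": "out",
  "simulation": {"n_subjects": 96, "n_genes": 2000, "k_true": 3,
                 "n_informative": 200, "effect_size": 2.0, "seed": 3},
  "B": 20, "n_init": 5,
  "adjustments": ["unadjusted", "prism_immunocompromised"],
  "seed": 3
}
EOF
cats run --config config.json
# selected k=3; report in out
```

`out/gap_curve.tsv` shows the selection evidence — the gap rises steeply
to k = 3 and then plateaus while the minimum cluster size collapses:

```
k  log_Wk   gap      s_k      min_cluster_size
1  12.2367  0.7162   0.0020   96
2  12.1865  0.7544   0.0021   36
3  12.1333  0.7959   0.0019   29
4  12.1216  0.7958   0.0020   14
```

The audit trail in `out/manifest.json` records the decision: the global
maximum was at k = 7, its CI overlapped k = 3..10, sizes eliminated
k ≥ 6, and parsimony picked k = 3. `out/models.tsv` holds the
subtype–outcome estimates (subtype 1 as reference); in this run the
discovered cluster 2 is the planted low-mortality group:

```
adjustment  model                term       estimate  p_value
unadjusted  mortality_logistic   subtype_2  0.035     0.0018
unadjusted  mortality_logistic   subtype_3  0.463     0.161
unadjusted  extubation_fine_gray subtype_2  4.195     3.7e-05
unadjusted  extubation_fine_gray subtype_3  2.811     0.0067
```

(an odds ratio < 1 means lower odds of death; a subdistribution hazard
ratio > 1 means a higher probability of extubation alive). Discovered
cluster indices are arbitrary, so the mapping to planted subtypes varies
by seed. `out/characterization.tsv` and `out/de_subtype_*.tsv` hold the
demographics-style table and per-subtype gene lists.

Every stage is also exposed individually (`cats simulate`, `cats
cluster`, `cats characterize`, `cats model`, `cats de`) and as plain
library functions (`cats_ards.gap_statistic`, `cats_ards.fit_fine_gray`,
…).

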