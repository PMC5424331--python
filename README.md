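# wingmorph

Landmark-based geometric morphometrics of insect wings, built for the
workflow used in taxonomic wing-shape studies of blow flies (Calliphoridae):
discriminating species, genera and sexes from the positions of homologous
vein-junction landmarks on the wing.

Given TPS landmark files (the tpsDig/tpsUtil dialect) and a specimen
metadata table, the package provides:

- **Procrustes superimposition** — generalized Procrustes analysis (GPA)
  removing translation, scale and rotation, with tangent-space projection
  at the consensus; centroid size `CS = sqrt(Σᵢ ‖xᵢ − x̄‖²)` as the size
  measure; averaging of repeated digitizations of each specimen.
- **Shape discrimination** — canonical variate analysis (CVA) maximising
  among-group relative to pooled within-group variation (at most g − 1
  axes for g groups); pairwise Mahalanobis distances
  `D = sqrt((μ₁ − μ₂)ᵀ W⁻¹ (μ₁ − μ₂))` and Procrustes distances between
  group mean shapes, each with permutation tests (p = (b + 1)/(rounds + 1));
  leave-one-out cross-validated nearest-group classification.
- **Size statistics** — Kruskal–Wallis H across species, pairwise
  Mann–Whitney U (exact when small and tie-free) with Bonferroni
  correction, and per-species sexual size dimorphism tests.
- **Allometry** — multivariate regression of shape on centroid size
  (optionally pooled within species or sex), the percentage of shape
  variation predicted by size, permutation tests, and allometry-free
  shapes for size-corrected reruns of every discrimination analysis.
- **Phenograms** — UPGMA clustering of the species Mahalanobis distance
  matrix with Newick export.
- **A synthetic wing generator** — multi-species landmark datasets with
  known species/sex/allometry structure and replicate digitization error,
  so the whole chain is testable end to end without real specimen data.

## Worked example

Simulate the default study design (12 species in 3 genera, 372 specimens,
19 landmarks digitized twice) and run the main analyses:

```python
import wingmorph as wm

spec = wm.blowfly_study(seed=1)
data = wm.generate_dataset(spec)
records = wm.parse_tps(data.tps)
table = wm.build_dataset(records, data.metadata)
aligned = wm.average_replicates(wm.gpa(table.coordinate_array(), meta=table.frame))

cva = wm.CanonicalVariates(aligned.shapes, aligned.meta["genus"].to_numpy()).fit()
print(cva.summary())

cls = wm.loo_classify(aligned.shapes, aligned.meta["species"].to_numpy())
print(cls.summary())

fit = wm.ShapeAllometry(
    aligned.shapes, aligned.centroid_sizes,
    pooling=aligned.meta["species"].to_numpy(),
).fit(rounds=999, seed=1)
print(fit.summary())
```

Output:

```
Canonical variate analysis
  groups: 3  specimens: 372  retained shape dims: 34
  axis   eigenvalue   % variance
  CV1       18.1450        75.64
  CV2        5.8443        24.36
Leave-one-out cross-validated classification
  CM: 100.0% (53/53)
  CC: 97.5% (39/40)
  ...
  overall: 99.5% (370/372)
Multivariate regression of shape on centroid size
  pooling: within_group   n = 372 (of 372)
  % predicted: 3.16
  permutation P (999 rounds): 0.001
```

With three genera the CVA yields exactly two canonical axes that together
carry 100% of the among-group variation; the leave-one-out table gives the
per-species identification accuracy a taxonomist would expect from these
wings; and the regression says that about 3% of shape variation in this
simulated population is size-related (allometry), significant but small —
so removing it barely changes the classification.

The same workflow is available from the shell:

```sh
wingmorph simulate --seed 1 --out-dir sim/
wingmorph run -c config.yaml      # full pipeline: CSV + Newick + run log
wingmorph classify --tps sim/wings.tps --metadata sim/metadata.csv --level species
```

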