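# radscreen

Radiogenomic association analysis for high-throughput radiation survival
screens of cancer cell lines.

Large panels of genomically annotated tumour cell lines can be irradiated
at a ladder of doses and read out by a luminescence proliferation assay.
`radscreen` turns those raw plates into per-line survival scores and asks
which genomic features — somatic copy-number alterations, gene mutations,
expression programs — track with survival after DNA damage. It is aimed at
computational biologists analysing pharmacogenomic/radiogenomic screens,
and ships a synthetic-cohort generator with planted ground truth so every
stage of the pipeline can be validated end to end.

## What it computes

**Integral survival.** A dose–response curve (survival fraction *f*(d)
relative to mock-irradiated wells at doses d = 1, 2, 3, 4, 5, 6, 8, 10 Gy)
is summarised by the trapezoidal area over log2 dose, rescaled to a 0–7
scale:

    IS = (7 / log2 10) · Σᵢ ½ [f(xᵢ) + f(xᵢ₊₁)] · (xᵢ₊₁ − xᵢ),   x = log2(dose)

0 means completely sensitive, 7 completely resistant. Clonogenic-assay
curves are summarised by the plain area under the curve on the linear dose
axis for cross-platform comparison.

**Copy-number features.** From segmented log2(CN/2) profiles (SEG files):
the fraction of the measured genome altered, fSCNA = Σ len(|log2 ratio| >
0.2) / Σ len — a genomic-instability surrogate; gene-level copy number as
the signed value of the overlapping segment with maximum |log2 ratio|; and
binary amplification (> 0.7) / deletion (< −0.7) calls.

**Information-coefficient association.** A feature x (0/1 mutation call or
continuous profile) is associated with the survival phenotype y through

    IC = sign(ρ) · sqrt(1 − exp(−2·Î))

where ρ is the (point-biserial) Pearson correlation and Î a kernel-density
estimate of the mutual information I(x; y). The IC lives in [−1, 1],
reduces to |r| for bivariate Gaussians, and remains sensitive to
non-linear dependence. Significance comes from an empirical permutation
test (two-sided by default; a directional variant is available). The
binary path is vectorised so thousand-feature screens and calibration
studies run in seconds.

**Expression programs.** ssGSEA projects each sample's expression profile
onto gene sets (GMT) as the integrated difference between the
rank-weighted in-set ECDF (weights rankᵅ, α = 0.25) and the uniform
out-of-set ECDF; median/SD-normalised signature summary scores implement
the "standard deviations from the median" pathway-activity recipe.

**Cohort statistics.** Per-lineage summaries and D'Agostino–Pearson K²
omnibus normality tests, plus plot-ready histogram / density / normal Q–Q
tables.

## Worked example

Simulate a 70-line cohort (two lineages) with one planted resistance
mutation — 20 % prevalence, a 2-cohort-SD survival shift, and seven
co-regulated genes — plus 25 null mutation features, then run the full
pipeline:

```python
from radscreen import (CohortConfig, LineageSpec, PlantedEffect,
                       RunConfig, run_pipeline)
from radscreen.simulate import GenomeModel

genome = GenomeModel.default(n_chromosomes=4, chromosome_length=50_000,
                             genes_per_chromosome=5, gene_length=1_000)
cohort = CohortConfig(
    lineages=(LineageSpec("LUAD", 40, 3.5, 0.8),
              LineageSpec("BREAST", 30, 3.0, 0.8)),
    planted_features=(PlantedEffect(
        "KEAP1", "mutation", prevalence=0.2, effect_size=2.0,
        linked_genes=tuple(f"G{i:04d}" for i in range(1, 8))),),
    n_null_features=25, noise_cv=0.1, seed=7, genome=genome)
run_pipeline(RunConfig(output_dir="demo_bundle", simulate=cohort,
                       n_perm=999, seed=7))
```

The mutation screen (`demo_bundle/ic_mutation.tsv`) ranks the planted
feature first, far ahead of the null features:

```
feature_id  ic                  p      n_carriers  direction   rank
KEAP1       0.4404950392083697  0.001  14          resistance  1
NULL0015    0.1896296432128569  0.05   12          resistance  2
NULL0022    0.16183141303288245 0.117  18          resistance  3
```

IC = 0.44 with the minimum attainable p (0.001 at 999 permutations) for
the planted resistance mutation; the best null feature reaches only
IC ≈ 0.19. The expression correlation table ranks the seven co-regulated
genes near the top (G0002, G0004, G0005, G0006, G0007, G0001, G0003 at
ranks 2–9, Spearman ρ ≈ 0.21–0.44); the null gene G0008 lands at rank 1
(ρ = 0.46) purely by sampling noise at this cohort size — a reminder that
single-gene correlations at n = 70 need the permutation machinery, not
just a ranking. Per-lineage summaries (`lineage_summary.tsv`) recover the
configured lineage means (LUAD 3.50, BREAST 3.24 for true means 3.5/3.0)
and ~3-fold within-lineage ranges.

Every table carries a provenance header (package version, config hash,
seed); rerunning with the same configuration reproduces the bundle
byte for byte.

The same stages are available from the shell:

```sh
radscreen simulate --config cohort.yaml --out cohort/
radscreen score-survival cohort/plates/LUAD_0000.tsv
radscreen fscna cohort/segments.seg
radscreen associate cohort/mutations.tsv scores.tsv --n-perm 999 --seed 7
radscreen run --config run.yaml
```

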