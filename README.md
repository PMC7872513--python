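# omiclocks

Multi-omics biological-age clocks, aging indicators, composite indices and
permutation-FDR association testing — exercised end-to-end on synthetic
cohorts with planted ground truth.

Biological age is an individual's age as read from molecular markers rather
than the calendar; the gap between the two ("age acceleration") is a
candidate summary of physiological wear. Studies that compare several such
clocks — telomere length, DNA-methylation, gene-expression, protein and
metabolite panels — need a substantial pipeline: per-layer preprocessing,
cross-validated penalized regression, age residualization, composite
construction, and multiple-testing control across hundreds of association
models. `omiclocks` implements that pipeline as a reusable, tested Python
library for methodologists and biostatisticians who want to study the
behaviour of five-clock analyses (power, calibration, composite gains)
under known, simulated truth. Real cohort data in the same TSV layout can
be analysed with the identical code path (`load_cohort` + the stage
functions); the synthetic generator is a first-class module, not a fixture.

## The method

For each omics layer with marker matrix **X** (subjects × markers) and
chronological age *y*:

1. **Preprocessing** — platform-specific missingness rules (median
   imputation for metabolite-like panels, detection-limit imputation for
   protein-like panels), residualization on technical covariates (batch,
   lab), and a per-marker quantile-normal transform
   Φ⁻¹((rank − ½)/n).
2. **Clock** — 10-fold cross-validation; within each training set markers
   are ranked by |cor(marker, age)| and the top-*k* enter a ridge regression
   (intercept unpenalized, penalty λ by inner 5-fold CV):
   min<sub>β</sub> ‖y − β₀ − Xβ‖² + λ‖β‖².
   The candidate *k* is chosen by a plateau rule — the smallest *k* whose
   out-of-fold correlation with age is within 0.01 of the best candidate.
   Held-out predictions ŷ are unbiased biological ages.
3. **Aging indicator** — the residual of ŷ on *y* (exactly orthogonal to
   age); for telomere length, the standardized −T/S ratio (shorter = older),
   not age-regressed.
4. **Composites** — on subjects with all five layers: the sum of z-scored
   indicators, and alternatively the first principal component of their
   correlation matrix (unit-norm loadings, positive sum).
5. **Associations** — one linear model per determinant × indicator pair
   with z-scored outcome and determinant (standardized β), sex as covariate
   (age additionally for telomere; sex becomes the outcome when it is the
   determinant), and sex-adjusted Spearman correlations between indicators.
6. **Permutation FDR** — phenotype rows are shuffled B times against the
   indicators; FDR(p) = mean #{p<sub>perm</sub> ≤ p} / #{p<sub>real</sub> ≤ p},
   and the significance threshold is the largest observed p with
   FDR(p) ≤ 5%.

The synthetic-data module plants the structure this machinery is meant to
find: age-correlated marker panels of very different sizes (1 to 20 000
markers), layer-specific unit-variance aging deviations with weak
(r < 0.2) cross-layer correlation, determinant effects on those deviations,
batch/lab offsets, detection-limit censoring, a telomere-like marker
declining with age, and 6-year mortality/onset outcomes. See
`docs/methods.md` for the full model and its limitations.

## Worked example

`examples/02_build_clock.py` simulates a 600-subject cohort with a
1000-marker epigenetic-like panel (80 informative markers, oracle R² = 0.8)
and trains a clock:

```
candidate marker counts and out-of-fold validation correlations:
  k=    0  r=-0.173
  k=   50  r=+0.804 <- selected (plateau rule)
  k=  200  r=+0.796
  k=  500  r=+0.792
  k= 1000  r=+0.797

out-of-fold cor(predicted age, chronological age) = 0.804
```

The k=0 row is the intercept-only baseline (its slightly negative
correlation is the hallmark of honest out-of-fold evaluation — predicting
the training-fold mean is anti-correlated with the held-out fold); 50
markers already reach the plateau, so the plateau rule stops there; 0.804
is the clock's accuracy on subjects its models never saw. The other
examples walk through cohort simulation (01), indicators and composites
(03), association testing with permutation FDR (04), and the full pipeline
with all artifacts (05).

A thin CLI mirrors the pipeline stages:

```bash
omiclocks run-all --outdir run1 --seed 7          # everything
omiclocks simulate --outdir run1 --seed 7         # ... or stage by stage
omiclocks build-clocks --layer epigenetic --outdir run1 --seed 7
```

All artifacts are TSV/JSON with the root seed and config hash stamped in a
header comment; identical (config, seed) gives byte-identical outputs.

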