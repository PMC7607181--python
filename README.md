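# metaboscore

Analysis toolkit for metabolic-phenotype profiling of tissue cohorts:

- **IHC combined scoring** (`metaboscore.scoring`): per-core combined score
  (intensity 0–3 × density 0–100 %, range 0–300), per-tumor mean score,
  positivity calling (cutoff ≥ 1), the combined PCK1+PCK2 score, four-way
  metabolic phenotype classification (glycolytic / gluconeogenic / mixed /
  unspecified from GLUT1, PCK1, PCK2 positivity), and cohort summary tables.
- **Margin vs. center quantification** (`metaboscore.margin`): optical-density
  conversion, H-DAB stain deconvolution (Ruifrok–Johnston), tissue
  segmentation, a 1 mm invasive-margin band via Euclidean distance transform
  (tumor-side only, technical cut edges excluded), saturated-DAB macrophage
  exclusion, DAB/hematoxylin area ratios normalized to the tumor center, and a
  one-sample t-test of log2 ratios across slides.
- **Cohort statistics** (`metaboscore.stats`), implemented from formulas:
  Mann–Whitney U (exact enumeration for small tie-free samples, tie-corrected
  normal approximation otherwise), Spearman correlation, Kaplan–Meier with
  Greenwood CIs, k-sample logrank, Cox proportional hazards (Newton–Raphson,
  Breslow ties), early-death exclusion filtering, median-split grouping.
- **Expression quantification** (`metaboscore.expression`): 2^ΔΔCp relative
  qPCR quantification against an 18S-like reference gene, and densitometry
  normalization to a loading control and reference sample.
- **Synthetic data** (`metaboscore.simulate`): TMA cohorts from a Gaussian
  copula with configurable positivity rates, PCK2–GLUT1 rank correlation,
  T-stage trends and phenotype-dependent exponential survival; H-DAB-like
  slides with a controllable margin/center DAB gradient, macrophage speckles
  and rectangular artefacts plus pixel-level truth masks; qPCR plates with
  known fold changes. All generators are deterministic given a seed.

## CLI

```bash
# synthetic data
metaboscore simulate cohort --seed 1 --out cohort/          # cores.csv, patients.csv, truth.json
metaboscore simulate slide  --seed 1 --out slide/           # slide.tif + mask PNGs + JSON sidecar
metaboscore simulate qpcr   --seed 1 --out cp.csv

# scoring pipeline
metaboscore score     --cores cohort/cores.csv --cutoff 1 --out scored.csv
metaboscore summarize --scored scored.csv --strata histology --out summary.csv
metaboscore phenotype --scored scored.csv --out phenotypes.csv

# margin vs center on one slide
metaboscore margin --image slide/slide.tif --tumor-mask slide/slide_tumor_mask.png \
    --mpp 8.0 --marker PCK2 --out quant.csv

# survival analysis (KM per group + logrank + Cox)
metaboscore survive --records cohort/patients.csv --group-by true_phenotype \
    --covariates stage,grade,age,gender --out survival/

# expression
metaboscore qpcr --table cp.csv --gene PCK2 --reference 18S --control control --out folds.csv
metaboscore densitometry --table bands.csv --reference-sample s1 --out dens.csv
```

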