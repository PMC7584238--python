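# qustex

Quantitative-ultrasound (QUS) texture-derivative radiomics, end to end:

1. **phantom_sim** — pulse-echo RF simulation from random point-scatterer
   fields with controllable scatterer size, number density and echogenicity,
   plus reference phantoms with analytically known backscatter and labelled
   two-class synthetic cohorts.
2. **spectral_qus** — per-window power spectra, reference-phantom
   normalization, and the five QUS parameters: mid-band fit (MBF), spectral
   slope (SS), 0-MHz intercept (SI), average scatterer diameter (ASD) and
   average acoustic concentration (AAC).
3. **parametric_maps** — tiling of the tumor ROI into 10-wavelength
   (≈ 2.2 mm) sub-ROIs at 94% overlap and assembly of the five parametric
   maps and their volume means.
4. **glcm_texture** — 16-level symmetric grey-level co-occurrence features
   (contrast, energy, correlation, homogeneity) with missing-pixel support:
   first-pass scalars and sliding texture maps from the parametric maps, and
   second-pass "texture derivatives" from the texture maps; 5 + 20 + 80 = 105
   named features per tumor.
5. **response_model** — balanced subsampling of an imbalanced cohort into
   seven subsets, sequential forward selection (≤ 3 features), FLD / KNN /
   RBF-SVM scorers, leave-one-out cross-validation, the
   sensitivity/specificity/PPV/NPV/accuracy/AUC panel, and univariate
   feature comparisons (Shapiro-Wilk gate → t-test / Mann-Whitney).
6. **pipeline + cli** — YAML configuration, HDF5 RF containers, CSV feature
   tables, JSON reports, and the `qustex` command line.

## CLI

```sh
qustex simulate --seed 1 --out cohort_dir/          # synthetic cohort + reference
qustex extract  --cohort cohort_dir/ --out features.csv
qustex classify --features features.csv --classifier knn --feature-set tex2 \
                --seed 17 --out report.json
qustex report   --features features.csv --out panels.json   # all 6 panels
```

All commands accept `--config config.yaml` (see `qustex.config.PipelineConfig`
for the schema; the committed defaults encode the acquisition and protocol
constants: 40 MHz sampling, 7 MHz center frequency, 4–9 MHz band, 10λ windows
at 94% overlap, 7 subsets, ≤ 3 features). Exit codes: 0 ok, 1 input error,
2 internal error.

## Library example

```python
from qustex.config import PipelineConfig
from qustex.pipeline import simulate_cohort, extract_cohort, classify_cohort

cfg = PipelineConfig()
cfg.sim.n_per_class = 5
cohort, reference = simulate_cohort(cfg, seed=1)
table = extract_cohort(cohort, reference, cfg)        # 10 x 105 feature table
report = classify_cohort(table, cfg, "knn", "tex2")   # LOOCV panel
print(report["panel"])
```
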