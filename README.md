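# thzcornea

Terahertz time-domain spectroscopy (THz-TDS) of the cornea: a tested,
reusable pipeline that discriminates intact from damaged corneal
endothelium using band-limited spectral-slope features and linear
support-vector-machine classification, together with a physics-based
generator of synthetic scan cohorts for exercising the analysis end to
end.

## The problem

The corneal endothelium is the inner cell monolayer that pumps excess
fluid out of the stroma. When it is damaged — for example by a
sustained rise in intraocular pressure (IOP) — the stroma swells, and
because liquid water dominates the dielectric response of soft tissue
in the 0.1–2 THz band, the reflected THz spectrum changes measurably.
The analysis here works on reflection-mode THz-TDS scans of whole eye
globes: a 9×9 grid of angular pixels, one scan every 4 min over a 9 h
pressure protocol (1 h acclimation at 15 mmHg, 4 h at 25/35/45 mmHg,
4 h back at 15 mmHg). Each sample carries an endothelial cell density
(ECD) label; densities above 3000 cells/mm² count as intact.

## The method

Per pixel and frame, the raw pulse is high-pass filtered (Gaussian,
half gain at 0.1 THz), Fourier transformed, and deconvolved against a
reference scan of a metallic sphere (R = 8.02 mm) of matching
curvature:

    H(f) = S(f) R*(f) / (|R(f)|² + λ²),    λ = 10⁻³ · max|R|

The feature is the ordinary least-squares slope of |H(f)| versus f over
0.4–0.8 THz — a dimensionless magnitude against THz, so the slope
carries units of picoseconds. Slopes are averaged over the central 25
pixels and over the last 30 min of each pressure period, giving three
predictors per sample: S_Start (acclimation), S_Elev (elevated IOP) and
S_Phys (post-elevation physiological IOP). A linear SVM (margin
penalty grid-searched by stratified cross-validation, features z-scored
on the training split) is evaluated over 300 randomized, stratified
70/30 splits; ROC curves are vertically averaged on a fixed 101-point
FPR grid and AUC is reported as mean ± SD over splits.

Because real ex vivo scans are not publicly available, the package
includes a first-class synthetic cohort generator built from standard
tissue optics: double-Debye water permittivity, symmetric Bruggeman
mixing of water and tissue background, an erfc hydration depth profile
(Fick's second law, semi-infinite medium) discretised into a layer
stack, and transfer-matrix reflectance at normal incidence shaping a
band-limited derivative-of-Gaussian reference pulse. Intact samples
(high ECD → efficient pump) show small, reversible slope excursions;
damaged samples accumulate water and keep it after the pressure drops.

## Worked example

`examples/water_reflectance.py` shows the physical contrast the whole
pipeline rides on:

```
double-Debye water at 0.5 THz: eps = 4.688+3.454j
fraction  |r(0.4 THz)|  band slope (ps)
    0.50        0.3925          -0.0732
    0.60        0.4062          -0.0886
    0.70        0.4204          -0.1040
    0.80        0.4351          -0.1195
    0.90        0.4501          -0.1348
```

A wetter surface reflects more strongly and its spectrum falls more
steeply with frequency: the band slope is a hydration biomarker.

`examples/pipeline_end_to_end.py` runs the full chain on six synthetic
samples:

```
sample_id  group_mmHg  ecd_cells_per_mm2  S_Start_ps  S_Elev_ps  S_Phys_ps
      S00        25.0          5085.2075     -0.1180    -0.1160    -0.1185
      S01        25.0           920.5091     -0.1160    -0.1337    -0.1350
      ...
        S_Start: AUC = 0.130 +/- 0.336 (100 splits)
         S_Elev: AUC = 1.000 +/- 0.000 (100 splits)
         S_Phys: AUC = 1.000 +/- 0.000 (100 splits)
  S_Elev+S_Phys: AUC = 1.000 +/- 0.000 (100 splits)

S_Phys vs S_Elev: r^2 = 0.970 (slope 0.94)
```

S_Start is measured before any pressure insult, so it carries no class
signal; S_Elev and S_Phys separate the classes, and their collinearity
reflects the persistence of damage after the pressure returns.

## Command line

The same stages are exposed as a thin CLI over the library:

```sh
thzcornea simulate --out run/                 # archive.h5 + labels.csv + manifest.json
thzcornea process  --archive run/archive.h5 --out run/slopes.csv
thzcornea features --slopes run/slopes.csv --labels run/labels.csv --out run/features.csv
thzcornea classify --features run/features.csv --out run/results --predictors elev,phys
thzcornea run-all  --config my.yaml --seed 7 --out run/
```

All parameters live in one YAML configuration; every output embeds a
SHA-256 hash of the resolved configuration, and a fixed master seed
makes the whole chain bit-reproducible.

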