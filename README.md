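# petlimit

Detection limits and quantification accuracy for PET imaging of
radiolabeled cells.

Direct cell labeling with ⁸⁹Zr (t½ = 78.4 h, e.g. as [⁸⁹Zr]Zr(oxinate)₄)
makes it possible to follow therapeutic cells — CAR-T products, engineered
lymphocytes — in vivo for days on clinical PET scanners. Before planning
such a study, two questions must be answered quantitatively:

1. **How few labeled cells can the scanner still detect**, as a function of
   the activity bound per cell (*specific activity*, SA, kBq/10⁶ cells) and
   of non-specific background radioactivity?
2. **How accurately is the activity of a small cell deposit measured**,
   given partial-volume losses, as a function of cell density
   (CD, 10⁶ cells/mL) and SA?

`petlimit` implements the complete in-vitro analysis chain for these
questions and a synthetic well-plate phantom generator to exercise it:

- **phantom simulation** (`petlimit.phantom`) — digital 6-well plates and a
  3×3 plate of 1 cm³ cubic wells loaded with ⁸⁹Zr-labeled cell suspensions;
  image formation as Gaussian point-spread blur + uniform ambient
  background + Poisson counting noise; gamma-counter measurements of each
  suspension.
- **quantification** (`petlimit.quantify`) — cylindrical/cubic volumes of
  interest, total well activity (mean concentration × VOI volume), and the
  contrast-to-noise ratio
  `CNR = (μ_well − μ_background) / σ_background`.
- **detection** (`petlimit.detection`) — the lower limit of detection
  (LLD) by threshold inversion through CNR regressions (95 % CI rule and
  Rose criterion CNR = 5), binomial logistic detection-probability curves
  `p(x) = 1/(1+e^{−(β₀+β₁x)})` in cell number `x`, and a
  non-specific-background simulation (background at 10–80 % of each well's
  concentration with Poisson-scaled noise, σ_b = √(k·μ_b)).
- **recovery** (`petlimit.recovery`) — recovery coefficients
  `RC = (measured − background)/known` and the log-linear partial-volume
  model `RC = a·ln(CD·SA) + γ₀ + u_scanner + ε`, with inversion
  `CD = exp((RC* − γ₀)/a)/SA` for study planning.
- **physics & statistics** (`petlimit.physics`) — ⁸⁹Zr decay arithmetic,
  Pearson correlation, Bland–Altman agreement.
- **orchestration** (`petlimit.study`, `petlimit.pipeline`, `petlimit` CLI)
  — end-to-end runs with provenance manifests.

## Worked example

```python
import petlimit as pl
from petlimit.study import quantify_study, analyze_detection

wells = quantify_study(pl.generate_study(pl.StudyConfig(seed=1)))
report = analyze_detection(wells, "petct")
print(report.lld.cnr_threshold, report.lld.lld_cells, report.prob_at_lld)
```

Running `python examples/02_lower_limit_of_detection.py` and
`python examples/03_detection_probability.py` prints (seed 1):

```
petct:
  CNR threshold (95% CI at SA=0): 83.8
  LLD: 3.2e+05 cells (5.45 kBq/1e6 cells)
  Rose-rule LLD: -1.44e+04 cells (0.701 kBq/1e6 cells)
...
detection probability at the LLD (3.2e+05 cells): 0.966

background simulation: 248 synthetic datasets (31 wells x 8 fractions)
fraction  detected/31   90%-point (cells)
  0.1        31          2.55e+04  (upper bound)
  ...
  0.8         7          2.38e+06
```

Reading: on this synthetic study the scanner needs ≈ 3×10⁵ cells (at the
study's specific activities) before the regression-predicted CNR clears
the noise-derived threshold of ≈ 84; at that cell number the fitted
probability of Rose-criterion detection is ≈ 0.97. The Rose rule alone
(CNR ≥ 5) is satisfied by essentially every studied load — an inversion at
or below zero cells means the limit lies below the observed range. As
non-specific background rises from 10 % to 80 % of the well concentration,
the cell number needed for 90 % detection probability grows from below
2.6×10⁴ (all wells detected) to ≈ 2.4×10⁶ — roughly two orders of
magnitude. `examples/04_recovery_model.py` fits the recovery model and
inverts the published coefficients (0.11, 0.57) at RC = 1, SA = 5.3,
giving 9.41×10⁶ cells/mL for full signal recovery.

One script per capability lives in `examples/`.

## Command line

```sh
petlimit run --out results/ --seed 1          # full pipeline
petlimit simulate --out sim/ --seed 1         # phantoms + well tables
petlimit lld --wells wells.csv --rule ci95_upper --out lld.json
petlimit detprob --wells wells.csv --scanner petct --out detprob.json
petlimit rc --wells wells.csv --out rcfit.json
petlimit rc-invert --fit rcfit.json --target 1.0 --sa 5.3
```

## Scope

The package models image formation phenomenologically (blur + background +
Poisson noise); it does not simulate sinograms, reconstruction,
attenuation, scatter or randoms, does not perform PSF-based partial-volume
correction, and does not model radiochemistry or cell viability. Images
are exchanged as NIfTI-1, tables as CSV, reports as JSON, configuration as
YAML. See `docs/methods.md` for the model details, parameter defaults and
known limitations.
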