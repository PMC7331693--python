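# xvlung

Regional lung-function quantification from time-resolved 3D lung images via
X-ray velocimetry (XV) analysis — built for researchers studying
muco-obstructive disease (cystic-fibrosis-like β-ENaC mouse models and
similar) who need *where* and *how unevenly* the lung ventilates, not just a
single global number.

Spirometry-style measures average airflow over the whole lung. XV instead
tracks the speckled lung texture across the breath: windowed 3D
cross-correlation between breath-phase volumes gives a tissue displacement
field, whose local volume change

```
fractional expansion = det(I + ∇u) − 1   (≡ ΔV_ROI / V_ROI, unitless)
```

maps ventilation per region of interest. The area-normalised histogram of
these values is then summarised by two scores:

* **HD (heterogeneous disease)** = `IQR / IQR_L` — the animal's expansion
  interquartile range over the mean littermate IQR. Healthy ≈ 1; patchy
  disease widens the histogram and raises HD.
* **CD (clustered disease)** = `(μ₂ − μ₁)/μ₂` from a least-squares
  double-Gaussian fit to the histogram — 0 for a single mode, rising toward
  1 as a distinct low-expansion mode (mucus-obstructed regions) splits off.

Alongside the regional maps the package computes the whole-lung volume/time
curve, the fractional tidal volume, and the expiratory time constant τ (time
from peak inspiration until 67% of tidal volume is expired), plus the
automation needed for large cohorts: mirror-symmetry auto-orientation and
cropping, threshold/morphology lung segmentation, and heart-blur QC flagging
of samples where cardiac motion defeated the velocimetry. A seeded synthetic
breathing-lung phantom with known ground truth stands in for animal data
end-to-end.

## Worked example

Score a synthetic cohort of three healthy littermates and three clustered
disease animals, end to end:

```python
from xvlung.pipeline import RunConfig, run_pipeline

config = RunConfig(
    out_dir="xv_run",
    seed=7,
    n_littermates=3,
    n_disease=3,
    disease_profile="clustered",
    grid_shape=(64, 64, 64),
    engine="truth",      # ground-truth displacement fields; "measured"
    window_size=8,       # runs the full cross-correlation engine
)
report = run_pipeline(config)
print(report.cohort.table[["id", "group", "iqr", "hd", "cd", "tau"]].round(4))
```

prints

```
 id      group    iqr     hd     cd    tau
L01 littermate 0.0237 0.9542 0.2388 0.1296
L02 littermate 0.0247 0.9954 0.1666 0.1296
L03 littermate 0.0260 1.0504 0.1951 0.1296
D01    disease 0.0507 2.0437 0.5580 0.1295
D02    disease 0.0462 1.8632 0.5413 0.1296
D03    disease 0.0504 2.0343 0.5764 0.1296
```

The littermates sit at HD ≈ 1 by construction (their mean is exactly 1 —
that is the definition of the normalisation) with the background CD level of
a unimodal histogram, while the clustered-disease animals double the
heterogeneity score and clearly separate in CD; τ ≈ 0.13 s reflects the
configured exponential expiration. `xv_run/` receives the cohort table
(CSV + JSON), a QC table, the config snapshot and a log; re-running with the
same seed reproduces the CSV byte for byte.

The model-fitting core is also usable directly, statsmodels-style:

```python
import numpy as np
from xvlung import DoubleGaussianModel, expansion_histogram

rng = np.random.default_rng(0)
values = np.r_[rng.normal(0.05, 0.01, 30_000), rng.normal(0.12, 0.01, 70_000)]
fit = DoubleGaussianModel(expansion_histogram(values, n_bins=50)).fit()
print(fit.summary())     # a1, mu1, sigma1, a2, mu2, sigma2, R^2, CD
```

A thin `xv` command line wraps the same library for shell use:
`xv simulate`, `xv preprocess`, `xv velocimetry`, `xv report` (exit codes:
0 success, 2 validation, 3 stage failure).

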