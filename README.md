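# disctilt

Quantifying optic disc tilt from circumpapillary OCT circle scans.

## The problem

Optic disc tilt is a hallmark of myopic eyes and confounds glaucoma
diagnostics (visual-field mean deviation, peripapillary RNFL thickness).
Classical tilt surrogates — the disc ovality ratio from fundus photographs,
or tilt angles measured in a single horizontal or vertical OCT plane — either
depend on disc shape or miss the plane of maximal tilt.

`disctilt` implements a direction-independent tilt metric: in the standard
3.4 mm RNFL circle scan the course of the retinal pigment epithelium (RPE),
displayed unrolled with both scan ends nasal and the middle temporal, forms
one wave per circumference when the disc is tilted against the optical axis.
That course, re-expressed with the center of the wave as the origin, is fit
by least squares to

    y = a · sin(b·x − c)

and the amplitude *a* (pixels) is the tilt metric: the more tilted the disc,
the larger the wave, whatever the tilt direction. The package provides the
full validation toolkit around the fit:

- **`disctilt.trace`** — RPE trace I/O (CSV), wave-centering, and extraction
  of the bright band from B-scan-like images;
- **`disctilt.sinefit`** — the sine fit as a scikit-learn regressor
  (`SineWaveRegressor`) plus `fit_sine` / `amplitude` / `tilt_direction` /
  `goodness` (R² with the strict > 0.90 quality gate);
- **`disctilt.ovality`** — the modified disc ovality ratio: rotating-calipers
  maximum/minimum diameters of the disc margin with the 45° vertical/
  horizontal axis rule (vertical disc → d_min/d_max ≤ 1, horizontal disc →
  d_max/d_min ≥ 1);
- **`disctilt.reliability`** — two-way absolute-agreement intraclass
  correlation ICC(A,1)/(A,k) with McGraw–Wong 95% CIs, Spearman rank
  correlation (mid-ranks, t-approximation or exact permutation p);
- **`disctilt.synthetic`** — generators for traces, rendered B-scan images,
  and cohorts with a specified Spearman correlation structure (Gaussian
  copula, `r = 2·sin(π·ρ/6)`);
- **`disctilt.cohort`** + the `disctilt` CLI — batch fitting and the full
  cohort analysis (summaries, ICCs, correlations, axis subgroups, fit
  quality).

## Worked example

Fit a synthetic 64-point RPE trace (true amplitude 42 px, 2 px plotting
noise) and read off the tilt metric:

```python
import numpy as np
from disctilt import (TraceSimSpec, simulate_trace, center_coordinates,
                      fit_sine, tilt_direction)

spec = TraceSimSpec(a_true=42.0, c_true=np.pi / 2, noise_sd=2.0,
                    n_points=64, seed=7)
trace = simulate_trace(spec)
fit = fit_sine(center_coordinates(trace))
print(f"amplitude a = {fit.a:.2f} px   (true 42.00)")
print(f"R^2 = {fit.r_squared:.4f}   quality gate (R^2 > 0.90): {fit.quality_pass}")
print(f"tilt direction = {np.degrees(tilt_direction(fit)):.1f} deg around the scan circle")
```

prints

```
amplitude a = 41.80 px   (true 42.00)
R^2 = 0.9971   quality gate (R^2 > 0.90): True
tilt direction = 188.6 deg around the scan circle
```

i.e. the fit recovers the simulated tilt to 0.2 px despite the noise, passes
the quality gate, and locates the most elevated meridian temporally
(~189° from the nasal scan start).

The same from the shell, end to end:

```sh
disctilt simulate fixtures --n-eyes 10 --seed 42   # traces/, images/, cohort.csv
disctilt fit fixtures/traces --out fits.csv        # per-eye a, b, c, R^2
disctilt cohort fixtures/cohort.csv                # full analysis report
```

The cohort report lists per-column summaries (e.g. amplitude
35.17 ± 16.15 px at the default study conditions), the intra-/inter-rater
ICCs (0.996 / 0.953 for seed 0), the four Spearman correlations of amplitude
with ovality ratio, spherical equivalent, axial length and body height, and
the vertical-/horizontal-axis subgroup correlations.

A deposited per-eye spreadsheet can be analyzed directly —
`disctilt --config columns.yaml cohort dataset.xlsx` — with `columns.yaml`
mapping canonical column names to the spreadsheet's headers (see
`data/README.md`).

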