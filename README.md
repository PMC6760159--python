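# bamf — Bayesian multiple-emitter fitting for SMLM

In single-molecule localization microscopy (SMLM), dense labeling or fast
acquisition produces frames where the images of several blinking
fluorophores overlap.  Fitting such clusters one emitter at a time
produces artifacts (including contrast inversion: dense regions appear
sparse), because the number of emitters in a cluster is itself unknown.

`bamf` treats multiple-emitter fitting as trans-dimensional Bayesian
inference.  A subregion of photon counts `D` is modeled as Poisson noise
around

```
lambda_k = b + a_x x_k + a_y y_k + sum_i Delta_k,i
```

where `Delta_k,i` is the integral over pixel `k` of a Gaussian PSF of
width `sigma_PSF` carrying `I_i` photons at `(x_i, y_i)`, and
`(b, a_x, a_y)` is a tilted background plane.  The posterior over
`theta = (x, y, I, N, b, a_x, a_y, l)` — including the emitter count `N`
and a per-emitter signal/background label `l` that lets PSF-sized kernels
absorb structured background — is sampled by reversible-jump MCMC with
birth/death, split/merge, generalized split/merge and label-conversion
jumps plus within-model moves, accepted by the
Metropolis–Hastings–Green rule.  Priors on intensity (an empirical KDE
fitted by a fast single-emitter pass), emitter density (`Poisson(rho W^2)`),
background offset (gamma) and plane tilt (standard normal) let strong
prior knowledge constrain the model where the likelihood alone cannot.

The output is twofold:

* a **posterior image** — the histogram of every sampled emitter
  position, carrying the uncertainty in the number of emitters; and
* a **MAPN table** — coordinates, intensities and standard errors from
  the most probable model (the modal signal-emitter count), refined by a
  fixed-model MCMC run.

It ships with a synthetic SMLM movie generator (blinking telegraph
kinetics with partial-exposure scaling, uniform/circle/two-emitter/
structured-background phantoms) and an evaluation harness (Hungarian
matching, Jaccard index, RMSE, two-emitter resolution scans).

## Worked example

```python
import numpy as np
from bamf import RunConfig, run_fit
from bamf.simulate import SimConfig, simulate
from bamf.evaluate import match, jaccard, rmse_accuracy

# a 24x24 px movie (100-nm pixels) of blinking 2,000-photon emitters on a
# 20-photon background, ~1.4 on-emitters per frame
sim = SimConfig(frame_size=24, n_frames=40, rho=1000.0,
                k_on=0.000144, k_off=0.4, seed=21)
movie, truth = simulate(sim)

result = run_fit(movie, config=RunConfig(rho=0.01), seed=2)
print(result.table[["frame", "x_px", "y_px", "se_x_px", "I_photons"]].head(3))

gt = truth.table()
m = match(result.table, gt[gt.photons > 500], threshold=1.2)
print(f"JAC = {jaccard(m):.2f}, RMSE = {rmse_accuracy(m):.3f} px")
```

prints

```
   frame      x_px       y_px   se_x_px    I_photons
0      1  7.748127  10.163022  0.047100  1334.773247
1      2  7.713218  10.102416  0.039286  1787.310641
2      2  9.902884  12.153206  0.067316  1143.022278
JAC = 0.82, RMSE = 0.115 px
```

Each row is one localized emitter in one frame: position in pixels (frame
coordinates), its posterior standard error (0.04–0.07 px here, i.e.
4–7 nm at 100-nm pixels; emitters on for part of a frame emit fewer
photons and localize less precisely), and the estimated photon count.
The Jaccard index scores detected-versus-true emitter overlap after
Hungarian matching at a 1.2-px gate; the RMSE is the distance of matched
pairs to the truth.

The same pipeline is available from the shell:

```sh
bamf simulate --out sim/ --seed 3
bamf fit sim/movie.tif --out results/ --seed 3
bamf evaluate --found results/localizations.csv --truth sim/truth.csv --threshold 1.2
```

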