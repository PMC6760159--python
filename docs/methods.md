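# Methods

## The model

A camera frame of single-molecule localization microscopy (SMLM) data is
modeled, after conversion to photon counts, as Poisson shot noise around a
per-pixel expectation

```
lambda_k = b + a_x * x_k + a_y * y_k + sum_i Delta_{k,i}
```

where `(b, a_x, a_y)` is a tilted plane of unstructured background and
`Delta_{k,i}` is the integral over pixel `k` of a normalized 2D Gaussian
point-spread function of half-width `sigma_PSF` centered on emitter `i`
with total intensity `I_i` photons per frame.  The pixel integral has the
closed form of a product of normal-CDF differences along each axis, so a
PSF image is an outer product of two 1D profiles; an experimentally
sampled PSF can be substituted as a unit-normalized lookup table evaluated
by bilinear interpolation (the Gaussian is the default and the only mode
exercised by the quantitative tests).

Each emitter carries a binary label: *signal* (a genuine blinking
fluorophore) or *background* (a PSF-sized kernel modeling structured,
out-of-focus fluorescence).  The likelihood is label-blind; only the
intensity priors distinguish the classes.

Pixel `(row r, col c)` has center `(x=c, y=r)` and covers
`[c-0.5, c+0.5] x [r-0.5, r+0.5]`, 0-based, in subregion-local
coordinates; conversion to frame coordinates happens once, at stitching.

## Priors

| parameter | prior | default hyperparameters |
|---|---|---|
| x, y | uniform over the subregion padded by `pad` px on every side | pad = 2 |
| N (emitter count, all labels) | Poisson(rho * W^2) | rho supplied by the user |
| I (signal) | kernel density estimate | fitted to single-emitter-pass intensities |
| I (background) | exponential | mean = mean signal intensity / bg_scale, bg_scale = 5 |
| b | gamma | moment-matched to single-emitter-pass backgrounds |
| a_x, a_y | normal(0, 1) | fixed |

The pad admits emitters just outside the subregion whose PSF tail still
falls on it.  The signal-intensity KDE lives on the log-intensity axis
(guaranteeing positive support) with a Gaussian kernel and Silverman
bandwidth; its sampler resamples a data point and adds kernel jitter.
Evaluation cost is bounded by thinning the fitted sample to at most 128
evenly spaced order statistics.  The standard workflow estimates the
empirical priors with a fast fixed-count single-emitter maximum-likelihood
pass (matched-filter detection, 7x7 ROIs, bounded quasi-Newton Poisson
MLE); `bg_scale = 5` reflects structured-background kernels being several
times dimmer than in-focus emitters and is a configuration knob, as is the
KDE bandwidth.

## The sampler

The chain explores the trans-dimensional space with three within-model
moves and four reversible jump pairs, accepted by the
Metropolis–Hastings–Green rule.  Every jump's acceptance includes the
ratio of the move-class probabilities of the current phase, so the two
members of a pair may have unequal probabilities; a schedule proposing a
class whose reverse has zero probability is rejected at construction.

Within-model moves (symmetric normal perturbations, Green factor 0):

* **single** — one emitter's `(x, y, I)`;
* **group** — a common `(x, y)` shift of all emitters within `2 sigma_PSF`
  of a chosen one, plus an intensity exchange between a random pair of the
  group (total group intensity conserved exactly); falls back to a single
  move for isolated emitters;
* **background** — `(b, a_x, a_y)`.

Jump pairs:

* **birth / death** — birth draws position and intensity from their
  priors, so those densities cancel in the acceptance and only the
  Poisson-count ratio and selection factors remain.  Death removes a
  uniformly chosen emitter; a background-labeled pick is auto-rejected
  (births create signal emitters only, so that death would have no
  reverse).
* **split / merge** — a split replaces `(x, y, I)` by two emitters with
  intensities `uI, (1-u)I` (`u ~ U(0,1)`) placed at
  `x ± {(1-u), u} d` with `d ~ N(0, sigma_PSF)` per axis, preserving the
  intensity-weighted centroid; the Jacobian of the map is `I`.  Merge
  inverts it for a uniformly chosen same-label pair within
  `2 sigma_PSF`; a split whose children land farther apart than the merge
  radius is auto-rejected (zero reverse density).
* **generalized split / merge** — the *gathering* direction takes a
  fraction `u_j ~ U(0, 1/2)` of the photons of each of the <=4 nearest
  signal emitters within `3 sigma_PSF` of a focal emitter (the focal
  included) and creates a new emitter at the photon-weighted centroid of
  the transfers plus `N(0, sigma_PSF)` jitter; the *scattering* direction
  deletes an emitter and distributes its photons over its <=4 nearest
  signal neighbors with uniform-Dirichlet weights.  The Jacobian is
  `prod(I_donors) / I_new^(m-1)`.  The forward selection probability sums
  over every focal choice that induces the same donor set, and the reverse
  feasibility conditions (the donee set of the new emitter equals the
  donor set; the reconstructed fractions respect the `1/2` cap) are
  checked explicitly — a violation means zero reverse density and
  auto-rejection.  These jumps mix dense regions where single birth/death
  steps stall.
* **conversion** — flips one emitter's signal/background label.  With
  probability 1/2 only the label flips (acceptance = intensity-prior
  density ratio; the likelihood cancels); otherwise the intensity is also
  redrawn from the destination label's prior, making the proposal
  densities cancel against the priors and the acceptance a pure likelihood
  ratio.  The redraw variant exists because with a narrow empirical signal
  prior the flip-only kernel makes the background label nearly absorbing
  once a kernel's intensity random-walks out of the signal prior's
  support; redrawing restores fast label mixing.  Both variants are
  reversible kernels and both are covered by the detailed-balance tests.

Each subregion runs a burn-in chain (default 3,000 jumps, class
probabilities 0.3/0.1/0.1/0.1/0.1/0.1/0.1/0.1 over in-model, birth, death,
split, merge, g-split, g-merge, conversion) and a post-burn-in chain
(2,000 jumps, 0.4/0.05/0.05/0/0/0.15/0.15/0.2) starting from the burn-in's
last state; dense data uses 20,000/10,000.  Chains start from the empty
model with the plane offset at the mean count — the burn-in's high
between-model probability is what discovers emitters.  Every chain is
bitwise reproducible from its seed; tiled runs derive one seed per
(global seed, frame, tile).

**Proposal-scale tuning.**  Position and intensity jump widths (defaults
0.075 px, 7.5 photons — the middle of the 0.05–0.1 px and 5–10 photon
working ranges; background offset 1 photon) are adapted by factors of 1.5
until short pilot chains accept 25–50% of within-model moves.  A
discovery pilot populates the model first, and the measurement pilots
propose within-model moves only, so the estimate is not diluted by a
near-empty model; adaptation ends before any recorded phase, preserving
detailed balance of the recorded chains.

## Post-processing

The most probable number of *signal* emitters (MAPN) is the mode over the
post chain, ties broken toward fewer emitters; background kernels are
nuisance structure and never count.  Because emitters within a sample are
exchangeable, MAPN samples are grouped into per-emitter clusters by
Hungarian assignment against running centroids initialized from the
highest-posterior sample — deterministic and invariant to emitter
permutation.  A fixed-model MCMC run (within-model moves only, labels
frozen, default 2,000 jumps) refines the best MAPN state before
clustering; cluster means and standard deviations become coordinates and
standard errors.  At 2,000 photons, sigma_PSF 1.2 px and 20-photon
background the single-emitter posterior width is ~0.03 px, which the
chain, the dense-grid oracle and the reported standard errors all agree
on.

Frames larger than one subregion are tiled (16 px tiles, 4 px overlap —
at least 3 sigma_PSF so a PSF core fits inside one tile's margin); core
rectangles bounded by overlap midpoints partition the frame exactly, and
stitching keeps a localization only from the tile whose half-open core
contains it.  Localizations with a standard error above 0.25 px are
filtered before rendering.  Two reconstructions are produced at 10x zoom:
the **posterior image** (position histogram of every signal emitter of
every post-chain sample, carrying model-count uncertainty) and the
**MAPN image** (unit-mass Gaussian blobs of width `max(se, 0.02 px)` per
localization, or a fixed width — 0.06 px for cross-method comparison).

## Synthetic data

The generator places emitters on a chosen structure — uniform field with
a 2-px empty border (density per um^2), circle circumference (density per
um), a fixed two-emitter pair, or a cross of signal emitters over a
static 18-kernel ring (radius 10 px, sigma 1.5 px, 400 photons) — and
switches each emitter by a continuous-time telegraph process with
exponential dwell times (off->on rate k_on, on->off rate k_off, initial
state stationary), binned to frames so a partially-on frame emits
proportionally fewer photons.  Rendering uses the same pixel-integrated
PSF as the forward model plus a uniform offset background and Poisson
noise.  Standard conditions are sigma_PSF 1.2 px, 2,000 photons/frame,
20-photon background, 100-nm pixels, k_off 0.4/frame; k_on is solved from
the stationary relation `rho_on ~ rho k_on/(k_on+k_off)` for a target
on-density.  What the generator does *not* emulate: camera excess noise
(EMCCD gain), drift, photobleaching, intensity variation between
fluorophores, and 3D defocus — so passing tests certify the inference
machinery under the stated noise model, not robustness to those effects.

## Reference studies and problem sizes

`bamf.benchmarks` reproduces the quantitative studies end to end; the
problem sizes are the package's desk-scale defaults:

* **Tuning band** — the standard 16x16 fixture holds five 2,000-photon
  emitters at fixed, resolvable positions (pairwise > 4 sigma_PSF;
  random placement would confound the count-recovery check with
  placement luck).
* **Circle phantom** — 200 frames of 10x10 px, radius `0.833 sigma_PSF`,
  ~4.5 on-emitters/frame, priors estimated from a sparse blinking
  calibration movie by the single-emitter pass.
* **Two-emitter resolution** — separations 0.10–1.50 sigma_PSF in 0.05
  steps, 50 constantly-on frames each, 10x10 px, chains reduced to
  3,000/1,500 jumps.  The intensity prior is *matched*: estimated from
  isolated constantly-on 2,000-photon emitters, because the study pair is
  too overlapped for the single-emitter pass — this narrow prior is what
  lets the model reject the one-emitter (4,000-photon) explanation at
  sub-PSF separations.  The resolution threshold is the smallest
  separation whose two-emitter fraction exceeds one half.

## Numerical choices and degenerate inputs

* `log(D_k!)` is precomputed per subregion (constant across states), and
  `-inf` uniformly encodes out-of-support states; proposals driving any
  expected count nonpositive are rejected through the likelihood.
* MAPN ties break toward fewer emitters; zero-variance clusters report
  `se = 0` and are removed by the uncertainty filter.
* Empty models fall through gracefully: within-model moves act on the
  background, death/split/conversion on an empty model count as rejected
  attempts, and an empty movie yields an empty localization table.
* The single-emitter MLE flags non-convergence (all-zero ROIs, boundary
  fits) instead of raising; prior construction requires >= 30 converged
  fits and otherwise instructs the user to supply a parametric prior.

## Known limitations

* Per-frame analysis only: no drift correction, no frame linking of
  re-blinking emitters, no temporal model.
* 2D Gaussian (or tabulated 2D) PSF only; no astigmatic/engineered 3D.
* The sCMOS per-pixel noise model is out of scope; data must be
  photon-converted with a scalar or per-pixel gain/offset.
* At very small separations the two-emitter fraction is prior-driven
  (the likelihood cannot distinguish the models at separation ~0), so the
  resolution threshold should be read together with the full curve.
* Chain-length defaults are tuned for sparse-to-moderate density; dense
  data needs the 20,000/10,000 schedule and proportionally more time.
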