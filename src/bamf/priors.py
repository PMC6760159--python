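"""Empirical prior construction from a fast single-emitter pass.

Before the trans-dimensional sampler runs, isolated emitters are detected
and fit frame by frame with an ordinary fixed-count maximum-likelihood fit
(one emitter, flat background, Poisson noise).  The fitted intensities feed
a kernel-density estimate that becomes the signal-intensity prior; the
fitted backgrounds set the gamma prior on the plane offset by moment
matching; the background-kernel intensity prior is an exponential whose
mean is the mean signal intensity divided by a user scaling constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

from .model import (
    PSFModel,
    PriorSet,
    Subregion,
    _LogIntensityKDE,
    emitter_pixel_counts,
)

__all__ = [
    "SingleFitResult",
    "detect_candidates",
    "fit_single",
    "build_intensity_prior",
    "build_prior_set",
    "estimate_priors",
]


@dataclass
class SingleFitResult:
    """Output of one single-emitter maximum-likelihood fit (frame coords)."""

    x: float
    y: float
    I: float
    b: float
    sigma_fit: float
    frame: int
    converged: bool
    se_x: float = np.nan
    se_y: float = np.nan
    se_I: float = np.nan


def detect_candidates(
    frames: np.ndarray,
    psf_sigma: float,
    detection_threshold: float,
) -> list[tuple[int, int, int]]:
    """Find candidate emitter pixels as (frame, row, col) triples.

    Each frame is median-subtracted and smoothed with a Gaussian matched to
    the PSF; local maxima of the filtered image above ``detection_threshold``
    survive a non-maximum suppression within a 2-sigma radius.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    radius = max(1, int(np.ceil(2.0 * psf_sigma)))
    out: list[tuple[int, int, int]] = []
    for t in range(frames.shape[0]):
        img = frames[t] - np.median(frames[t])
        filt = ndimage.gaussian_filter(img, psf_sigma, mode="nearest")
        local_max = ndimage.maximum_filter(filt, size=2 * radius + 1, mode="nearest")
        peaks = (filt >= local_max) & (filt > detection_threshold)
        for r, c in zip(*np.nonzero(peaks)):
            out.append((t, int(r), int(c)))
    return out


def _neg_loglik(params: np.ndarray, data: np.ndarray, sigma: float, fit_sigma: bool):
    if fit_sigma:
        x, y, logI, b, logsig = params
        sigma = float(np.exp(logsig))
    else:
        x, y, logI, b = params
    I = float(np.exp(logI))
    region = Subregion(data, pad=0.0)
    try:
        lam = b + emitter_pixel_counts(x, y, I, PSFModel(sigma), region)
    except ValueError:
        return np.inf
    if np.any(lam <= 0):
        return np.inf
    return float(np.sum(lam - data * np.log(lam)))


def fit_single(
    roi: Subregion,
    psf: PSFModel,
    frame: int = 0,
    fit_sigma: bool = False,
) -> SingleFitResult:
    """Maximum-likelihood fit of one emitter on a flat background.

    Optimizes (x, y, I, b) -- and optionally sigma -- against the Poisson
    likelihood with a quasi-Newton iteration (intensity and width on a log
    scale to keep them positive).  Standard errors come from the inverse of
    the finite-difference observed Fisher information.  Degenerate inputs
    are flagged as non-converged, never raised.
    """
    data = roi.data
    h, w = data.shape
    total = float(data.sum())
    b0 = max(float(np.median(data)), 1e-2)
    I0 = max(total - b0 * data.size, 10.0)
    # centroid of background-subtracted counts as the position start
    excess = np.clip(data - b0, 0.0, None)
    if excess.sum() > 0:
        ys, xs = np.mgrid[0:h, 0:w]
        x0 = float((xs * excess).sum() / excess.sum())
        y0 = float((ys * excess).sum() / excess.sum())
    else:
        x0, y0 = (w - 1) / 2.0, (h - 1) / 2.0
    p0 = [x0, y0, np.log(I0), b0]
    bounds = [(-1.0, w), (-1.0, h), (np.log(1.0), np.log(1e7)), (1e-3, None)]
    if fit_sigma:
        p0.append(np.log(psf.sigma))
        bounds.append((np.log(0.3), np.log(5.0)))
    res = optimize.minimize(
        _neg_loglik,
        np.asarray(p0, dtype=np.float64),
        args=(data, psf.sigma, fit_sigma),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 200},
    )
    x, y, logI, b = res.x[:4]
    I = float(np.exp(logI))
    sigma_fit = float(np.exp(res.x[4])) if fit_sigma else psf.sigma
    converged = bool(res.success) and np.isfinite(res.fun) and I > 0 and b >= 0
    # a fit drifting outside the ROI (plus margin) is unusable downstream
    if not (-1 <= x <= w and -1 <= y <= h):
        converged = False
    se = (np.nan, np.nan, np.nan)
    if converged:
        se = _fisher_se(res.x, data, psf.sigma, fit_sigma, I)
        if not np.all(np.isfinite(se)):
            converged = False
    ox, oy = roi.origin
    return SingleFitResult(
        x=float(x) + oy,
        y=float(y) + ox,
        I=I,
        b=float(b),
        sigma_fit=sigma_fit,
        frame=frame,
        converged=converged,
        se_x=se[0],
        se_y=se[1],
        se_I=se[2],
    )


def _fisher_se(params, data, sigma, fit_sigma, I):
    """Standard errors of (x, y, I) from the observed Fisher information."""
    n = len(params)
    eps = 1e-4
    hess = np.zeros((n, n))
    f0 = _neg_loglik(params, data, sigma, fit_sigma)
    for i in range(n):
        for j in range(i, n):
            pi = params.copy()
            pi[i] += eps
            pj = params.copy()
            pj[j] += eps
            pij = pi.copy()
            pij[j] += eps
            hess[i, j] = hess[j, i] = (
                _neg_loglik(pij, data, sigma, fit_sigma)
                - _neg_loglik(pi, data, sigma, fit_sigma)
                - _neg_loglik(pj, data, sigma, fit_sigma)
                + f0
            ) / eps**2
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return (np.nan, np.nan, np.nan)
    d = np.diag(cov)
    if np.any(d[:3] <= 0):
        return (np.nan, np.nan, np.nan)
    # delta method for I = exp(logI)
    return (float(np.sqrt(d[0])), float(np.sqrt(d[1])), float(np.sqrt(d[2])) * I)


def build_intensity_prior(
    intensities: Sequence[float],
    bandwidth_rule: str = "silverman",
    bandwidth: Optional[float] = None,
) -> _LogIntensityKDE:
    """Smoothed kernel-density estimate of the signal intensity prior.

    The KDE lives on the log-intensity axis, which keeps the support of the
    density strictly positive; Silverman's rule sets the bandwidth unless an
    explicit one is given.
    """
    intensities = np.asarray(list(intensities), dtype=np.float64)
    if len(intensities) < 30:
        raise ValueError(
            f"only {len(intensities)} intensity samples; at least 30 are needed "
            "for a stable KDE -- pass a parametric intensity prior instead"
        )
    if bandwidth is None and bandwidth_rule != "silverman":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    return _LogIntensityKDE(intensities, bandwidth=bandwidth)


def build_prior_set(
    fits: Sequence[SingleFitResult],
    rho: float,
    region_width: float,
    bg_scale: float = 5.0,
    min_fits: int = 30,
) -> PriorSet:
    """Assemble the full prior set from converged single-emitter fits.

    * gamma prior on the plane offset by moment matching on the fitted
      backgrounds (shape = mean^2/var, scale = var/mean);
    * signal-intensity KDE from the fitted intensities;
    * exponential background-kernel intensity prior with mean
      ``mean(I)/bg_scale``;
    * Poisson emitter-count prior with mean ``rho * region_width**2``.
    """
    good = [f for f in fits if f.converged and f.I > 0 and f.b >= 0]
    if len(good) < min_fits:
        raise ValueError(
            f"only {len(good)} converged fits; need >= {min_fits} to build "
            "empirical priors -- lower the detection threshold or supply "
            "parametric priors"
        )
    I = np.array([f.I for f in good])
    b = np.array([f.b for f in good])
    b_mean = float(np.mean(b))
    b_var = float(np.var(b, ddof=1))
    if b_var <= 0:
        b_var = max(b_mean, 1e-6)  # Poisson-like fallback for degenerate scatter
    kde = build_intensity_prior(I)
    return PriorSet(
        n_mean=rho * region_width**2,
        offset_shape=b_mean**2 / b_var,
        offset_scale=b_var / b_mean,
        signal_intensity=kde,
        bg_intensity_mean=float(np.mean(I)) / bg_scale,
    )


def estimate_priors(
    frames: np.ndarray,
    psf: PSFModel,
    rho: float,
    region_width: float,
    bg_scale: float = 5.0,
    detection_threshold: float = 50.0,
    roi_size: int = 7,
    max_fits: int = 2000,
) -> PriorSet:
    """End-to-end empirical prior estimation from a photon-count stack."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    cands = detect_candidates(frames, psf.sigma, detection_threshold)
    half = roi_size // 2
    fits: list[SingleFitResult] = []
    for t, r, c in cands:
        if len(fits) >= max_fits:
            break
        r0, c0 = r - half, c - half
        r1, c1 = r0 + roi_size, c0 + roi_size
        if r0 < 0 or c0 < 0 or r1 > frames.shape[1] or c1 > frames.shape[2]:
            continue
        roi = Subregion(frames[t, r0:r1, c0:c1], origin=(r0, c0), pad=0.0)
        fits.append(fit_single(roi, psf, frame=t))
    return build_prior_set(fits, rho, region_width, bg_scale=bg_scale)
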