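"""Forward model for pixelated SMLM frames.

A frame (or subregion of a frame) of photon counts is modeled as a tilted
plane of unstructured background plus a sum of pixel-integrated Gaussian
point-spread functions, one per emitter, observed through Poisson shot
noise.  Emitters carry a binary label: *signal* emitters are genuine
blinking fluorophores, *background* emitters are PSF-sized kernels used to
absorb structured (out-of-focus) background.  The label does not enter the
likelihood -- only the priors on intensity distinguish the two classes.

Everything here is expressed as log-densities so that the sampler can work
with sums and ``-inf`` encodes "out of support".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, ndtr

__all__ = [
    "SIGNAL",
    "BACKGROUND",
    "Subregion",
    "EmitterSet",
    "BackgroundPlane",
    "ModelState",
    "PSFModel",
    "PriorSet",
    "emitter_pixel_counts",
    "expected_counts",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]

# Emitter labels.  Integers so the label vector is a compact array.
SIGNAL = 1
BACKGROUND = 0

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class InvalidParameterError(ValueError):
    """A model parameter is outside its physical domain."""


class InvalidDataError(ValueError):
    """Observed counts are not nonnegative integers."""


class InvalidStateError(ValueError):
    """A model state implies a nonpositive expected count somewhere."""


@dataclass
class Subregion:
    """A rectangle of photon-count data cut from a camera frame.

    Coordinates are subregion-local: pixel ``(row r, col c)`` has center
    ``(x=c, y=r)`` and covers ``[c-0.5, c+0.5] x [r-0.5, r-0.5+1]``.
    Emitters may live up to ``pad`` pixels beyond each edge, where part of
    their PSF still falls on the data.
    """

    data: np.ndarray
    origin: tuple[int, int] = (0, 0)  # (row, col) offset in the full frame
    pad: float = 2.0

    # caches -- constant across sampler states
    _log_fact: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _xedges: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _yedges: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.size == 0:
            raise InvalidDataError("subregion data must be a nonempty 2D array")
        if self.pad < 0:
            raise InvalidParameterError("pad must be >= 0")
        if not np.all(np.isfinite(self.data)):
            raise InvalidDataError("subregion data must be finite")
        if np.any(self.data < 0):
            raise InvalidDataError("photon counts must be nonnegative")
        self._log_fact_sum = None
        self._xcenters = None
        self._ycenters = None

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def xlim(self) -> tuple[float, float]:
        """Support of the emitter x-position prior (subregion-local)."""
        return (-self.pad, self.width - 1 + self.pad)

    @property
    def ylim(self) -> tuple[float, float]:
        return (-self.pad, self.height - 1 + self.pad)

    @property
    def support_area(self) -> float:
        (x0, x1), (y0, y1) = self.xlim, self.ylim
        return (x1 - x0) * (y1 - y0)

    def log_factorial(self) -> np.ndarray:
        """log(D_k!) per pixel, precomputed once (constant across states)."""
        if self._log_fact is None:
            d = np.round(self.data)
            if np.any(np.abs(d - self.data) > 1e-9):
                raise InvalidDataError("photon counts must be integers")
            self._log_fact = gammaln(d + 1.0)
        return self._log_fact

    def log_factorial_sum(self) -> float:
        if self._log_fact_sum is None:
            self._log_fact_sum = float(self.log_factorial().sum())
        return self._log_fact_sum

    def pixel_edges(self) -> tuple[np.ndarray, np.ndarray]:
        if self._xedges is None:
            self._xedges = np.arange(self.width + 1, dtype=np.float64) - 0.5
            self._yedges = np.arange(self.height + 1, dtype=np.float64) - 0.5
        return self._xedges, self._yedges

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcastable x (1, W) and y (H, 1) pixel-center grids."""
        if self._xcenters is None:
            self._xcenters = np.arange(self.width, dtype=np.float64)[None, :]
            self._ycenters = np.arange(self.height, dtype=np.float64)[:, None]
        return self._xcenters, self._ycenters


@dataclass
class EmitterSet:
    """Positions, intensities and labels of the emitters of one model state."""

    x: np.ndarray
    y: np.ndarray
    I: np.ndarray
    label: np.ndarray  # SIGNAL or BACKGROUND per emitter

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=np.float64))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=np.float64))
        self.I = np.atleast_1d(np.asarray(self.I, dtype=np.float64))
        self.label = np.atleast_1d(np.asarray(self.label, dtype=np.int8))
        n = len(self.x)
        if not (len(self.y) == len(self.I) == len(self.label) == n):
            raise InvalidParameterError("emitter arrays must share one length")

    @classmethod
    def empty(cls) -> "EmitterSet":
        z = np.empty(0)
        return cls(z, z.copy(), z.copy(), np.empty(0, dtype=np.int8))

    @classmethod
    def _fast(cls, x, y, I, label) -> "EmitterSet":
        # hot-path constructor: arrays already validated float64/int8
        obj = object.__new__(cls)
        obj.x, obj.y, obj.I, obj.label = x, y, I, label
        return obj

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_signal(self) -> int:
        return int(np.count_nonzero(self.label == SIGNAL))

    def copy(self) -> "EmitterSet":
        return EmitterSet._fast(
            self.x.copy(), self.y.copy(), self.I.copy(), self.label.copy()
        )


@dataclass
class BackgroundPlane:
    """Tilted-plane unstructured background: b + a_x * x + a_y * y."""

    b: float = 0.0
    a_x: float = 0.0
    a_y: float = 0.0

    def copy(self) -> "BackgroundPlane":
        return BackgroundPlane(self.b, self.a_x, self.a_y)

    def image(self, region: Subregion) -> np.ndarray:
        xs, ys = region.pixel_centers()
        return self.b + self.a_x * xs + self.a_y * ys


@dataclass
class ModelState:
    """One point in the trans-dimensional parameter space."""

    emitters: EmitterSet
    background: BackgroundPlane

    def copy(self) -> "ModelState":
        return ModelState(self.emitters.copy(), self.background.copy())

    @classmethod
    def background_only(cls, b: float) -> "ModelState":
        return cls(EmitterSet.empty(), BackgroundPlane(b=b))


@dataclass
class PSFModel:
    """2D Gaussian PSF of half-width ``sigma`` (pixels), integrated per pixel.

    Optionally an experimentally sampled PSF can be supplied as a
    unit-normalized lookup table on a subpixel grid; it is then evaluated by
    bilinear interpolation and scaled by the emitter intensity.
    """

    sigma: float
    numeric_psf: Optional[np.ndarray] = None
    numeric_step: float = 0.1  # subpixel sampling step of the lookup table

    def __post_init__(self):
        if self.sigma <= 0:
            raise InvalidParameterError("sigma_psf must be > 0")
        if self.numeric_psf is not None:
            tab = np.asarray(self.numeric_psf, dtype=np.float64)
            if np.any(tab < 0):
                raise InvalidParameterError("numeric PSF must be nonnegative")
            s = tab.sum()
            if s <= 0:
                raise InvalidParameterError("numeric PSF must have positive mass")
            # normalize to unit *integral* over its support
            self.numeric_psf = tab / (s * self.numeric_step**2)


def emitter_pixel_counts(
    x_i: float, y_i: float, I_i: float, psf: PSFModel, region: Subregion
) -> np.ndarray:
    """Expected photons per pixel from a single emitter.

    The pixel integral of the normalized 2D Gaussian has the closed form
    ``I * [Phi((x_k+.5-x_i)/s) - Phi((x_k-.5-x_i)/s)] * [same in y]`` with
    ``Phi`` the standard normal CDF; the x and y factors separate, so the
    image is an outer product of two 1D profiles.
    """
    if I_i <= 0:
        raise InvalidParameterError("emitter intensity must be > 0")
    if psf.numeric_psf is not None:
        return I_i * _numeric_psf_image(x_i, y_i, psf, region)
    xe, ye = region.pixel_edges()
    cx = np.diff(ndtr((xe - x_i) / psf.sigma))
    cy = np.diff(ndtr((ye - y_i) / psf.sigma))
    return I_i * np.outer(cy, cx)


def _numeric_psf_image(x_i: float, y_i: float, psf: PSFModel, region: Subregion) -> np.ndarray:
    """Bilinear lookup of a tabulated PSF centered at (x_i, y_i), per pixel."""
    tab = psf.numeric_psf
    h, w = tab.shape
    step = psf.numeric_step
    # table sample (r, c) corresponds to offset ((r - (h-1)/2) * step, ...)
    ys = (np.arange(region.height) - y_i) / step + (h - 1) / 2.0
    xs = (np.arange(region.width) - x_i) / step + (w - 1) / 2.0
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    r0 = np.clip(np.floor(yy).astype(int), 0, h - 2)
    c0 = np.clip(np.floor(xx).astype(int), 0, w - 2)
    fr = np.clip(yy - r0, 0.0, 1.0)
    fc = np.clip(xx - c0, 0.0, 1.0)
    inside = (yy >= 0) & (yy <= h - 1) & (xx >= 0) & (xx <= w - 1)
    val = (
        tab[r0, c0] * (1 - fr) * (1 - fc)
        + tab[r0 + 1, c0] * fr * (1 - fc)
        + tab[r0, c0 + 1] * (1 - fr) * fc
        + tab[r0 + 1, c0 + 1] * fr * fc
    )
    return np.where(inside, val, 0.0)


def sum_emitter_counts(emitters: EmitterSet, psf: PSFModel, region: Subregion) -> np.ndarray:
    """Sum of per-emitter expected images (signal and background alike)."""
    out = np.zeros_like(region.data)
    if len(emitters) == 0:
        return out
    if psf.numeric_psf is not None:
        for xi, yi, Ii in zip(emitters.x, emitters.y, emitters.I):
            out += emitter_pixel_counts(xi, yi, Ii, psf, region)
        return out
    xe, ye = region.pixel_edges()
    s = psf.sigma
    # vectorized over emitters: CDF differences along each axis
    fx = ndtr((xe[None, :] - emitters.x[:, None]) / s)
    fy = ndtr((ye[None, :] - emitters.y[:, None]) / s)
    cx = fx[:, 1:] - fx[:, :-1]
    cy = fy[:, 1:] - fy[:, :-1]
    return np.einsum("i,ir,ic->rc", emitters.I, cy, cx)


def expected_counts(state: ModelState, psf: PSFModel, region: Subregion) -> np.ndarray:
    """Per-pixel expected photons: tilted plane plus all emitters' PSFs."""
    lam = state.background.image(region) + sum_emitter_counts(state.emitters, psf, region)
    if np.any(lam <= 0):
        raise InvalidStateError("expected counts must be positive at every pixel")
    return lam


def log_likelihood(state: ModelState, psf: PSFModel, region: Subregion) -> float:
    """Poisson log-likelihood of the subregion data under the state.

    Labels do not appear: signal- and background-labeled emitters contribute
    identically to the expected counts.  A state implying a nonpositive
    expected count anywhere has zero likelihood (``-inf``).
    """
    log_fact_sum = region.log_factorial_sum()
    lam = state.background.image(region) + sum_emitter_counts(
        state.emitters, psf, region
    )
    if lam.min() <= 0:
        return -np.inf
    return float(np.sum(region.data * np.log(lam) - lam)) - log_fact_sum


class _LogIntensityKDE:
    """Gaussian KDE on log-intensity, used as the empirical signal prior.

    Working on the log axis keeps the support positive; the density on the
    intensity axis carries the 1/I change-of-variables factor.
    """

    #: evaluation-cost cap; a KDE over more fit results is thinned to this
    MAX_SAMPLES = 128

    def __init__(self, intensities: Sequence[float], bandwidth: Optional[float] = None):
        s = np.asarray(intensities, dtype=np.float64)
        if np.any(s <= 0):
            raise InvalidParameterError("intensity samples must be > 0")
        if len(s) > self.MAX_SAMPLES:
            # deterministic thinning: evenly spaced order statistics keep the
            # density shape while bounding the per-evaluation cost
            s = np.sort(s)[
                np.linspace(0, len(s) - 1, self.MAX_SAMPLES).round().astype(int)
            ]
        self.log_samples = np.log(s)
        n = len(s)
        if bandwidth is None:
            # Silverman's rule on the log axis
            sd = np.std(self.log_samples, ddof=1) if n > 1 else 0.0
            bandwidth = 1.06 * max(sd, 1e-3) * n ** (-1 / 5)
        self.bandwidth = float(bandwidth)
        self._norm = np.log(n) + np.log(self.bandwidth) + _LOG_SQRT_2PI

    @property
    def mean(self) -> float:
        """Mean of the fitted density on the intensity axis."""
        # lognormal kernel mean: exp(mu_i + h^2/2) averaged over kernels
        return float(np.mean(np.exp(self.log_samples + 0.5 * self.bandwidth**2)))

    def logpdf(self, I) -> np.ndarray:
        I = np.atleast_1d(np.asarray(I, dtype=np.float64))
        if I.min() > 0:  # fast path: all in support
            logI = np.log(I)
            z2 = ((logI[:, None] - self.log_samples) / self.bandwidth) ** 2
            m = z2.min(axis=1)
            lse = -0.5 * m + np.log(np.exp(-0.5 * (z2 - m[:, None])).sum(axis=1))
            return lse - self._norm - logI
        out = np.full(I.shape, -np.inf)
        ok = I > 0
        if np.any(ok):
            out[ok] = self.logpdf(I[ok])
        return out

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        idx = rng.integers(0, len(self.log_samples), size=n)
        return np.exp(self.log_samples[idx] + self.bandwidth * rng.standard_normal(n))


@dataclass
class PriorSet:
    """All prior distributions of the model, with their hyperparameters.

    Components: uniform position over the padded subregion; Poisson prior on
    the emitter count with mean ``n_mean = rho * W**2``; gamma prior on the
    background offset; standard-normal priors on the plane slopes; an
    empirical (KDE) prior on signal intensity; an exponential prior on
    background-kernel intensity with mean = mean signal intensity / bg_scale.
    """

    n_mean: float
    offset_shape: float
    offset_scale: float
    signal_intensity: _LogIntensityKDE
    bg_intensity_mean: float
    slope_sigma: float = 1.0

    def __post_init__(self):
        if self.n_mean <= 0:
            raise InvalidParameterError("n_mean must be > 0")
        if self.offset_shape <= 0 or self.offset_scale <= 0:
            raise InvalidParameterError("gamma prior parameters must be > 0")
        if self.bg_intensity_mean <= 0:
            raise InvalidParameterError("background intensity mean must be > 0")
        k = np.arange(128)
        self._log_n_table = [
            float(v) for v in k * np.log(self.n_mean) - self.n_mean - gammaln(k + 1.0)
        ]

    # -- individual log-densities (kept separate so tests can sum them) --

    def log_n(self, n: int) -> float:
        if n < 128:
            return self._log_n_table[n]
        return float(n * np.log(self.n_mean) - self.n_mean - gammaln(n + 1.0))

    def log_offset(self, b: float) -> float:
        if b <= 0:
            return -np.inf
        k, th = self.offset_shape, self.offset_scale
        return float((k - 1) * np.log(b) - b / th - gammaln(k) - k * np.log(th))

    def log_slope(self, a: float) -> float:
        return float(-0.5 * (a / self.slope_sigma) ** 2 - np.log(self.slope_sigma) - _LOG_SQRT_2PI)

    def log_signal_I(self, I) -> np.ndarray:
        return self.signal_intensity.logpdf(I)

    def log_background_I(self, I) -> np.ndarray:
        I = np.atleast_1d(np.asarray(I, dtype=np.float64))
        out = np.full(I.shape, -np.inf)
        ok = I > 0
        out[ok] = -np.log(self.bg_intensity_mean) - I[ok] / self.bg_intensity_mean
        return out

    def sample_background_I(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.exponential(self.bg_intensity_mean, size=n)


def log_prior(state: ModelState, priors: PriorSet, region: Subregion) -> float:
    """Joint log-prior of a model state; ``-inf`` encodes out-of-support."""
    em = state.emitters
    n = len(em)
    bg = state.background
    if bg.b <= 0:
        return -np.inf
    total = (
        priors.log_n(n)
        + priors.log_offset(bg.b)
        + priors.log_slope(bg.a_x)
        + priors.log_slope(bg.a_y)
    )
    if n:
        (x0, x1), (y0, y1) = region.xlim, region.ylim
        x, y, I = em.x, em.y, em.I
        if (
            x.min() < x0 or x.max() > x1
            or y.min() < y0 or y.max() > y1
            or I.min() <= 0
        ):
            return -np.inf
        total -= n * np.log(region.support_area)
        sig = em.label == SIGNAL
        n_sig = int(sig.sum())
        if n_sig == n:
            total += float(priors.log_signal_I(I).sum())
        elif n_sig == 0:
            total += float(priors.log_background_I(I).sum())
        else:
            total += float(priors.log_signal_I(I[sig]).sum())
            total += float(priors.log_background_I(I[~sig]).sum())
    return total


def log_posterior(
    state: ModelState, psf: PSFModel, region: Subregion, priors: PriorSet
) -> float:
    """Unnormalized log-posterior: log-likelihood + log-prior."""
    lp = log_prior(state, priors, region)
    if np.isinf(lp):
        return -np.inf
    return log_likelihood(state, psf, region) + lp
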