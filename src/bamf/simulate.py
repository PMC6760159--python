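"""Synthetic SMLM movie generation with ground truth.

Emitters are placed on a chosen structure (uniform field, circle,
two-emitter pair, or a cross of signal emitters over a static ring of
dimmer out-of-focus kernels), switched on and off by a continuous-time
telegraph process with exponential dwell times, and rendered through the
pixel-integrated Gaussian PSF onto a uniform background with Poisson shot
noise.  An emitter that is on for only part of a frame's exposure emits
proportionally fewer photons in that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import PSFModel, Subregion, emitter_pixel_counts

__all__ = [
    "SimConfig",
    "GroundTruth",
    "place_emitters",
    "blinking_trace",
    "solve_kon",
    "render_frames",
    "simulate",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic movie.

    ``rho`` is the labeled-emitter density: per um^2 for the uniform and
    cross structures, per um of circumference for the circle structure.
    Structure-specific fields are ignored for other structures.
    """

    frame_size: int = 24
    n_frames: int = 100
    pixel_nm: float = 100.0
    sigma_psf: float = 1.2          # px
    intensity: float = 2000.0       # photons/frame when fully on
    background: float = 20.0        # photons/px
    k_on: float = 0.1               # per frame
    k_off: float = 0.4              # per frame
    rho: float = 1000.0
    structure: str = "uniform"      # uniform | circle | two_emitter | cross_plus_ring
    circle_radius: float = 1.0      # px
    separation: float = 0.3         # px, two_emitter
    always_on: bool = False
    border: float = 2.0             # px left empty at the frame edges
    ring_radius: float = 10.0       # px, cross_plus_ring background ring
    ring_n: int = 18
    ring_sigma: float = 1.5         # px
    ring_intensity: float = 400.0   # photons/frame
    seed: int = 0

    def __post_init__(self):
        if self.k_on < 0 or self.k_off < 0 or (self.k_on + self.k_off) <= 0:
            raise ValueError("switching rates must be >= 0 and not both zero")


@dataclass
class GroundTruth:
    """Emitter positions, nominal photon rates and per-frame occupancy."""

    x: np.ndarray               # frame coordinates, px
    y: np.ndarray
    intensity: np.ndarray       # photons/frame when fully on
    sigma: np.ndarray           # per-emitter PSF width, px
    occupancy: np.ndarray       # (n_emitters, n_frames), fraction of exposure on
    structure: np.ndarray = field(default=None)  # "signal" or "background" tag

    def __post_init__(self):
        if self.structure is None:
            self.structure = np.full(len(self.x), "signal", dtype=object)

    def __len__(self):
        return len(self.x)

    def table(self) -> pd.DataFrame:
        """Per-frame table of every emitter with nonzero occupancy."""
        rows = []
        for t in range(self.occupancy.shape[1]):
            occ = self.occupancy[:, t]
            for i in np.nonzero(occ > 0)[0]:
                rows.append(
                    {
                        "frame": t,
                        "x": float(self.x[i]),
                        "y": float(self.y[i]),
                        "photons": float(self.intensity[i] * occ[i]),
                        "structure": self.structure[i],
                    }
                )
        return pd.DataFrame(rows, columns=["frame", "x", "y", "photons", "structure"])


def place_emitters(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw emitter positions (x, y) in pixels for the configured structure."""
    w = config.frame_size
    px_um = config.pixel_nm / 1000.0
    if config.structure == "uniform":
        side = (w - 2 * config.border) * px_um
        n = rng.poisson(config.rho * side**2)
        lo, hi = config.border, w - 1 - config.border
        return np.column_stack([rng.uniform(lo, hi, n), rng.uniform(lo, hi, n)])
    if config.structure == "circle":
        r = config.circle_radius
        n = max(1, rng.poisson(config.rho * 2 * np.pi * r * px_um))
        th = rng.uniform(0, 2 * np.pi, n)
        cx = cy = (w - 1) / 2.0
        return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
    if config.structure == "two_emitter":
        cx = cy = (w - 1) / 2.0
        h = config.separation / 2.0
        return np.array([[cx - h, cy], [cx + h, cy]])
    if config.structure == "cross_plus_ring":
        # signal emitters uniform on a cross-shaped mask
        side = (w - 2 * config.border) * px_um
        n = rng.poisson(config.rho * side**2)
        lo, hi = config.border, w - 1 - config.border
        arm = max(1.0, 0.1 * (hi - lo))  # cross arm half-width, px
        cx = cy = (w - 1) / 2.0
        pts = []
        while len(pts) < n:
            x = rng.uniform(lo, hi)
            y = rng.uniform(lo, hi)
            if abs(x - cx) <= arm or abs(y - cy) <= arm:
                pts.append((x, y))
        return np.asarray(pts) if pts else np.empty((0, 2))
    raise ValueError(f"unknown structure {config.structure!r}")


def blinking_trace(
    k_on: float, k_off: float, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame on-occupancy of a two-state telegraph process.

    Dwell times are exponential: mean 1/k_on in the off state, 1/k_off in
    the on state (rates per frame).  The initial state is drawn from the
    stationary distribution.  The returned occupancy is the fraction of
    each frame's exposure spent in the on state, so partially-on frames
    yield proportionally scaled photon counts.
    """
    if k_on < 0 or k_off < 0 or (k_on + k_off) <= 0:
        raise ValueError("rates must be >= 0 and not both zero")
    p_on = k_on / (k_on + k_off)
    on = rng.uniform() < p_on
    occ = np.zeros(n_frames)
    t = 0.0
    while t < n_frames:
        rate = k_off if on else k_on
        dwell = np.inf if rate == 0 else rng.exponential(1.0 / rate)
        t_end = min(t + dwell, n_frames)
        if on:
            f0, f1 = int(t), int(np.ceil(t_end))
            for f in range(f0, min(f1, n_frames)):
                occ[f] += min(t_end, f + 1) - max(t, f)
        t = t_end
        if not np.isfinite(dwell) and t >= n_frames:
            break
        on = not on
    return np.clip(occ, 0.0, 1.0)


def solve_kon(rho: float, rho_on: float, k_off: float) -> float:
    """Switching-on rate that yields a target stationary on-density.

    From the telegraph stationarity relation rho_on ~ rho * k_on/(k_on+k_off):
    ``k_on = k_off * rho_on / (rho - rho_on)``.
    """
    if not (0 < rho_on < rho):
        raise ValueError("need 0 < rho_on < rho")
    return k_off * rho_on / (rho - rho_on)


def _make_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    pos = place_emitters(config, rng)
    n = len(pos)
    if config.always_on or config.structure == "two_emitter":
        occ = np.ones((n, config.n_frames))
    else:
        occ = np.vstack(
            [blinking_trace(config.k_on, config.k_off, config.n_frames, rng) for _ in range(n)]
        ) if n else np.zeros((0, config.n_frames))
    truth = GroundTruth(
        x=pos[:, 0],
        y=pos[:, 1],
        intensity=np.full(n, config.intensity),
        sigma=np.full(n, config.sigma_psf),
        occupancy=occ,
    )
    if config.structure == "cross_plus_ring":
        th = 2 * np.pi * np.arange(config.ring_n) / config.ring_n
        c = (config.frame_size - 1) / 2.0
        truth = GroundTruth(
            x=np.concatenate([truth.x, c + config.ring_radius * np.cos(th)]),
            y=np.concatenate([truth.y, c + config.ring_radius * np.sin(th)]),
            intensity=np.concatenate(
                [truth.intensity, np.full(config.ring_n, config.ring_intensity)]
            ),
            sigma=np.concatenate([truth.sigma, np.full(config.ring_n, config.ring_sigma)]),
            occupancy=np.vstack(
                [truth.occupancy, np.ones((config.ring_n, config.n_frames))]
            ) if len(truth) else np.ones((config.ring_n, config.n_frames)),
            structure=np.concatenate(
                [truth.structure, np.full(config.ring_n, "background", dtype=object)]
            ),
        )
    return truth


def render_frames(
    truth: GroundTruth, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-noisy photon-count movie from a ground truth."""
    w = config.frame_size
    region = Subregion(np.zeros((w, w)), pad=0.0)
    movie = np.empty((config.n_frames, w, w), dtype=np.int64)
    psfs = {s: PSFModel(s) for s in np.unique(truth.sigma)} if len(truth) else {}
    for t in range(config.n_frames):
        lam = np.full((w, w), float(config.background))
        occ = truth.occupancy[:, t] if len(truth) else np.empty(0)
        for i in np.nonzero(occ > 0)[0]:
            lam += emitter_pixel_counts(
                truth.x[i], truth.y[i], truth.intensity[i] * occ[i],
                psfs[truth.sigma[i]], region,
            )
        movie[t] = rng.poisson(lam)
    return movie


def simulate(config: SimConfig, rng=None) -> tuple[np.ndarray, GroundTruth]:
    """Generate a movie and its ground truth under one configuration."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    truth = _make_truth(config, rng)
    movie = render_frames(truth, config, rng)
    return movie, truth
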