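"""From chains to localizations and reconstructions.

The post-burn-in chain visits models with different emitter counts.  The
most probable number of signal emitters (MAPN) selects the model; its
samples are clustered into per-emitter groups, optionally refined with a
fixed-model MCMC run, and summarized into coordinates with standard
errors.  Subregion results are stitched by keeping each localization only
from the tile whose core rectangle contains it, and two reconstructions
are produced: the posterior image (a histogram over *all* sampled models)
and the MAPN image (Gaussian blobs at the summarized coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import ndtr

from .model import SIGNAL, ModelState, PSFModel, PriorSet, Subregion
from .sampler import (
    Chain,
    ChainSample,
    JumpSchedule,
    ProposalScales,
    _run_phase,
)
from .model import log_posterior

__all__ = [
    "TABLE_COLUMNS",
    "Tile",
    "PosteriorImage",
    "mapn_extract",
    "cluster_mapn",
    "mcmc_refine",
    "summarize",
    "tile_frame",
    "stitch",
    "render_posterior",
    "render_mapn",
    "filter_localizations",
    "empty_table",
]

TABLE_COLUMNS = [
    "frame", "x_px", "y_px", "se_x_px", "se_y_px",
    "I_photons", "se_I", "label", "tile",
]


def empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: [] for c in TABLE_COLUMNS})


@dataclass
class Tile:
    """One overlapping subregion of a frame plus its core rectangle.

    ``core`` is (row_lo, row_hi, col_lo, col_hi) in frame coordinates with
    half-open [lo, hi) convention; the cores of all tiles exactly partition
    the frame.
    """

    region: Subregion
    core: tuple[float, float, float, float]
    index: int


@dataclass
class PosteriorImage:
    """Accumulated position histogram at ``zoom`` x upsampling."""

    data: np.ndarray
    zoom: int


def mapn_extract(post_chain: Chain) -> tuple[int, list[ChainSample]]:
    """Most probable number of *signal* emitters and its chain samples.

    Ties are broken toward the smaller count.  Background-labeled emitters
    model structured background and never count toward the model order.
    """
    if len(post_chain) == 0:
        raise ValueError("post chain is empty")
    counts = post_chain.n_signal_trace()
    n_star = int(np.bincount(counts).argmax())  # argmax returns the smallest tie
    samples = [s for s, n in zip(post_chain.samples, counts) if n == n_star]
    return n_star, samples


def cluster_mapn(samples: Sequence[ChainSample], n_star: int) -> list[dict]:
    """Group the signal emitters of MAPN samples into per-emitter clusters.

    Emitter order within a sample is arbitrary (the posterior is exchange-
    symmetric), so each sample's emitters are matched to running cluster
    centroids by optimal assignment on squared distance.  Centroids start
    from the highest-log-posterior sample, making the result independent of
    sample order and of any emitter permutation.
    """
    if n_star == 0 or not samples:
        return []
    best = max(samples, key=lambda s: s.log_posterior)
    sig = best.state.emitters.label == SIGNAL
    cx = best.state.emitters.x[sig].astype(float).copy()
    cy = best.state.emitters.y[sig].astype(float).copy()
    clusters = [{"x": [], "y": [], "I": []} for _ in range(n_star)]
    counts = np.zeros(n_star)
    for s in samples:
        em = s.state.emitters
        m = em.label == SIGNAL
        x, y, I = em.x[m], em.y[m], em.I[m]
        cost = (x[:, None] - cx[None, :]) ** 2 + (y[:, None] - cy[None, :]) ** 2
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            clusters[c]["x"].append(x[r])
            clusters[c]["y"].append(y[r])
            clusters[c]["I"].append(I[r])
            counts[c] += 1
            w = 1.0 / counts[c]
            cx[c] = (1 - w) * cx[c] + w * x[r]
            cy[c] = (1 - w) * cy[c] + w * y[r]
    for cl in clusters:
        for k in cl:
            cl[k] = np.asarray(cl[k])
    return clusters


def mcmc_refine(
    region: Subregion,
    psf: PSFModel,
    priors: PriorSet,
    mapn_state: ModelState,
    jumps: int = 2000,
    scales: Optional[ProposalScales] = None,
    rng_seed=0,
) -> Chain:
    """Fixed-model MCMC started from the best MAPN sample.

    Only within-model moves run (single, group, background); the emitter
    count and all labels are frozen, so this is ordinary MCMC inside the
    most probable model space.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    scales = scales or ProposalScales()
    schedule = JumpSchedule(
        burnin_probs=(1.0, 0, 0, 0, 0, 0, 0, 0),
        post_probs=(1.0, 0, 0, 0, 0, 0, 0, 0),
        burnin_jumps=0,
        post_jumps=jumps,
    )
    state = mapn_state.copy()
    lp = log_posterior(state, psf, region, priors)
    if not np.isfinite(lp):
        raise ValueError("MAPN state has zero posterior probability")
    chain, _, _ = _run_phase(
        "post", jumps, state, lp, region, psf, priors, schedule, scales, rng
    )
    return chain


def summarize(
    clusters: Sequence[dict],
    frame: int = 0,
    origin: tuple[int, int] = (0, 0),
    tile: int = 0,
) -> pd.DataFrame:
    """Per-cluster means and standard deviations -> localization rows.

    Coordinates are shifted from subregion-local to frame coordinates by
    the subregion origin.
    """
    rows = []
    orow, ocol = origin
    for cl in clusters:
        if len(cl["x"]) == 0:
            continue
        rows.append(
            {
                "frame": frame,
                "x_px": float(np.mean(cl["x"])) + ocol,
                "y_px": float(np.mean(cl["y"])) + orow,
                "se_x_px": float(np.std(cl["x"])),
                "se_y_px": float(np.std(cl["y"])),
                "I_photons": float(np.mean(cl["I"])),
                "se_I": float(np.std(cl["I"])),
                "label": "signal",
                "tile": tile,
            }
        )
    if not rows:
        return empty_table()
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def tile_frame(
    frame: np.ndarray,
    tile_size: int = 16,
    overlap: int = 4,
    pad: float = 2.0,
) -> list[Tile]:
    """Cut a frame into overlapping square tiles whose cores partition it.

    The stride is ``tile_size - overlap``; core boundaries sit at the
    midpoints of the overlap bands.  A frame smaller than one tile yields a
    single tile.
    """
    if overlap >= tile_size / 2:
        raise ValueError("overlap must be < tile_size/2")
    frame = np.asarray(frame)
    h, w = frame.shape

    def _origins(extent: int) -> list[int]:
        if extent <= tile_size:
            return [0]
        stride = tile_size - overlap
        n = int(np.ceil((extent - tile_size) / stride)) + 1
        return [min(i * stride, extent - tile_size) for i in range(n)]

    def _bounds(origins: list[int], extent: int) -> list[tuple[float, float]]:
        size = min(tile_size, extent)
        edges = [0.0]
        for a, b in zip(origins[:-1], origins[1:]):
            edges.append((b + a + size) / 2.0)
        edges.append(float(extent))
        return list(zip(edges[:-1], edges[1:]))

    r_origins, c_origins = _origins(h), _origins(w)
    r_bounds, c_bounds = _bounds(r_origins, h), _bounds(c_origins, w)
    tiles = []
    idx = 0
    for r0, (rlo, rhi) in zip(r_origins, r_bounds):
        for c0, (clo, chi) in zip(c_origins, c_bounds):
            data = frame[r0 : r0 + tile_size, c0 : c0 + tile_size]
            # pixel-center convention: pixel row r covers [r-0.5, r+0.5)
            core = (rlo - 0.5, rhi - 0.5, clo - 0.5, chi - 0.5)
            tiles.append(Tile(Subregion(data, origin=(r0, c0), pad=pad), core, idx))
            idx += 1
    return tiles


def stitch(tables: Sequence[pd.DataFrame], cores: Sequence[tuple]) -> pd.DataFrame:
    """Keep each localization only from the tile whose core contains it.

    Cores use the half-open convention [lo, hi), so a localization exactly
    on a boundary belongs to exactly one tile.
    """
    kept = []
    for tab, (rlo, rhi, clo, chi) in zip(tables, cores):
        if len(tab) == 0:
            continue
        m = (
            (tab["y_px"] >= rlo)
            & (tab["y_px"] < rhi)
            & (tab["x_px"] >= clo)
            & (tab["x_px"] < chi)
        )
        kept.append(tab[m])
    if not kept:
        return empty_table()
    return pd.concat(kept, ignore_index=True)


def render_posterior(
    tile_chains: Sequence[tuple[Chain, tuple[int, int], tuple]],
    frame_shape: tuple[int, int],
    zoom: int = 10,
) -> PosteriorImage:
    """Histogram of all sampled signal-emitter positions at ``zoom`` x.

    Every post-chain sample contributes its signal emitters (background
    kernels are excluded); positions in a tile's overlap margin are dropped
    so each emitter is counted from one tile only.  Summing these images
    over frames gives the average posterior reconstruction.
    """
    h, w = frame_shape
    img = np.zeros((h * zoom, w * zoom))
    for chain, (orow, ocol), core in tile_chains:
        rlo, rhi, clo, chi = core
        xs, ys = [], []
        for s in chain.samples:
            em = s.state.emitters
            m = em.label == SIGNAL
            if np.any(m):
                xs.append(em.x[m])
                ys.append(em.y[m])
        if not xs:
            continue
        x = np.concatenate(xs) + ocol
        y = np.concatenate(ys) + orow
        keep = (y >= rlo) & (y < rhi) & (x >= clo) & (x < chi)
        ix = np.floor((x[keep] + 0.5) * zoom).astype(int)
        iy = np.floor((y[keep] + 0.5) * zoom).astype(int)
        ok = (ix >= 0) & (ix < w * zoom) & (iy >= 0) & (iy < h * zoom)
        np.add.at(img, (iy[ok], ix[ok]), 1.0)
    return PosteriorImage(img, zoom)


def render_mapn(
    table: pd.DataFrame,
    frame_shape: tuple[int, int],
    zoom: int = 10,
    se_floor: float = 0.02,
    fixed_sigma: Optional[float] = None,
) -> np.ndarray:
    """Sum of unit-mass Gaussian blobs at the localized coordinates.

    Per-axis blob widths are ``max(se, se_floor)`` unless ``fixed_sigma``
    is given, which renders every localization at the same width (the
    convention used for cross-method comparisons).
    """
    h, w = frame_shape
    img = np.zeros((h * zoom, w * zoom))
    step = 1.0 / zoom
    for row in table.itertuples():
        sx = fixed_sigma if fixed_sigma is not None else max(row.se_x_px, se_floor)
        sy = fixed_sigma if fixed_sigma is not None else max(row.se_y_px, se_floor)
        x, y = row.x_px, row.y_px
        # integrate the Gaussian over subpixel bins within +-5 sigma
        c0 = max(0, int(np.floor((x - 5 * sx + 0.5) * zoom)))
        c1 = min(w * zoom, int(np.ceil((x + 5 * sx + 0.5) * zoom)) + 1)
        r0 = max(0, int(np.floor((y - 5 * sy + 0.5) * zoom)))
        r1 = min(h * zoom, int(np.ceil((y + 5 * sy + 0.5) * zoom)) + 1)
        if c1 <= c0 or r1 <= r0:
            continue
        xe = np.arange(c0, c1 + 1) * step - 0.5
        ye = np.arange(r0, r1 + 1) * step - 0.5
        gx = np.diff(ndtr((xe - x) / sx))
        gy = np.diff(ndtr((ye - y) / sy))
        img[r0:r1, c0:c1] += np.outer(gy, gx)
    return img


def filter_localizations(table: pd.DataFrame, max_se: float = 0.25) -> pd.DataFrame:
    """Drop localizations whose x or y standard error exceeds ``max_se`` px."""
    if len(table) == 0:
        return table
    m = (table["se_x_px"] <= max_se) & (table["se_y_px"] <= max_se)
    return table[m].reset_index(drop=True)
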