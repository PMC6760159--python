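"""Camera calibration, run configuration and standard-format I/O."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import PriorSet, _LogIntensityKDE

__all__ = [
    "CameraCalibration",
    "RunConfig",
    "to_photons",
    "read_movie",
    "write_movie",
    "save_priors",
    "load_priors",
]


@dataclass
class CameraCalibration:
    """ADU-to-photon conversion: photons = (raw - offset) / gain."""

    gain: float = 1.0        # ADU per photon
    offset: float = 0.0      # ADU
    gain_map: Optional[np.ndarray] = None    # optional per-pixel maps
    offset_map: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


def to_photons(raw: np.ndarray, cal: CameraCalibration) -> np.ndarray:
    """Convert a raw ADU stack to integer photon counts.

    Counts are clipped below at zero and rounded to the nearest integer
    (the Poisson likelihood needs integer data).  A stack where most
    pixels clip warns about a likely calibration problem.
    """
    raw = np.asarray(raw, dtype=np.float64)
    gain = cal.gain_map if cal.gain_map is not None else cal.gain
    offset = cal.offset_map if cal.offset_map is not None else cal.offset
    photons = (raw - offset) / gain
    clipped = np.mean(photons < 0)
    if clipped > 0.5:
        warnings.warn(
            f"{clipped:.0%} of pixels fall below the camera offset; "
            "check the gain/offset calibration",
            stacklevel=2,
        )
    return np.round(np.clip(photons, 0, None))


@dataclass
class RunConfig:
    """All tunable settings of a fitting run, with standard defaults."""

    sigma_psf: Union[float, str] = 1.2   # px, or "estimate"
    rho: float = 0.01                    # expected emitters per pixel
    bg_scale: float = 5.0                # signal-mean / background-mean intensity ratio
    tile_size: int = 16                  # px
    overlap: int = 4                     # px
    pad: float = 2.0                     # px beyond each subregion edge
    burnin_jumps: int = 3000
    post_jumps: int = 2000
    refine_jumps: int = 2000
    burnin_probs: tuple = (0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1)
    post_probs: tuple = (0.4, 0.05, 0.05, 0.0, 0.0, 0.15, 0.15, 0.2)
    sigma_xy: float = 0.075              # px, initial within-model jump size
    sigma_I: float = 7.5                 # photons
    sigma_b: float = 1.0                 # photons
    max_se: float = 0.25                 # px, localization filter threshold
    zoom: int = 10                       # reconstruction upsampling
    detection_threshold: float = 50.0    # photons, single-emitter candidate cut
    seed: int = 0

    def __post_init__(self):
        if self.tile_size < 8:
            raise ValueError("tile_size must be >= 8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("burnin_probs", "post_probs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["burnin_probs"] = list(self.burnin_probs)
        d["post_probs"] = list(self.post_probs)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def read_movie(path) -> np.ndarray:
    """Read a multi-page TIFF (or a directory of single-page TIFFs)."""
    path = Path(path)
    if path.is_dir():
        pages = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not pages:
            raise FileNotFoundError(f"no TIFF files in {path}")
        return np.stack([tifffile.imread(p) for p in pages])
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_movie(path, movie: np.ndarray) -> None:
    tifffile.imwrite(
        path, np.asarray(movie, dtype=np.float32), photometric="minisblack"
    )


def save_priors(priors: PriorSet, outdir) -> None:
    """Write a PriorSet as plain text: hyperparameters + intensity samples."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {
        "n_mean": priors.n_mean,
        "offset_shape": priors.offset_shape,
        "offset_scale": priors.offset_scale,
        "bg_intensity_mean": priors.bg_intensity_mean,
        "slope_sigma": priors.slope_sigma,
        "kde_bandwidth": priors.signal_intensity.bandwidth,
    }
    (outdir / "prior_params.json").write_text(json.dumps(params, indent=2))
    pd.DataFrame(
        {"intensity": np.exp(priors.signal_intensity.log_samples)}
    ).to_csv(outdir / "intensity_samples.csv", index=False)


def load_priors(indir) -> PriorSet:
    indir = Path(indir)
    params = json.loads((indir / "prior_params.json").read_text())
    samples = pd.read_csv(indir / "intensity_samples.csv")["intensity"].to_numpy()
    kde = _LogIntensityKDE(samples, bandwidth=params.pop("kde_bandwidth"))
    return PriorSet(signal_intensity=kde, **params)
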