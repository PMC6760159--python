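"""Reference study protocols on synthetic data.

Each function reproduces one of the quantitative synthetic-data studies
end to end -- generating the movie, estimating priors where the protocol
calls for it, running the sampler and measuring the result.  They are
used by the acceptance script and tests, and serve as worked examples of
driving the package programmatically.

Standard conditions throughout: sigma_PSF = 1.2 px, 2,000 photons per
fully-on emitter per frame, 20-photon offset background, 100-nm pixels,
k_off = 0.4 per frame.
"""

from __future__ import annotations

import numpy as np

from .io import RunConfig
from .model import PSFModel, PriorSet, Subregion, emitter_pixel_counts
from .pipeline import fit_frame_counts, run_fit
from .priors import estimate_priors
from .sampler import JumpSchedule, ProposalScales, run_chain, tune_scales
from .simulate import SimConfig, simulate, solve_kon

__all__ = [
    "FIVE_EMITTER_X",
    "FIVE_EMITTER_Y",
    "five_emitter_region",
    "blinking_calibration_priors",
    "matched_intensity_priors",
    "tuned_within_model_acceptance",
    "circle_standard_error_mode",
    "two_emitter_resolution",
]

SIGMA_PSF = 1.2
INTENSITY = 2000.0
BACKGROUND_OFFSET = 20.0
K_OFF = 0.4

# the standard 16x16 convergence fixture: five resolvable 2,000-photon
# emitters (pairwise separations > 4 sigma_PSF)
FIVE_EMITTER_X = np.array([3.2, 11.5, 3.8, 11.2, 7.6])
FIVE_EMITTER_Y = np.array([3.5, 4.1, 11.8, 11.3, 7.4])


def five_emitter_region(seed: int, pad: float = 2.0) -> Subregion:
    """One Poisson realization of the standard five-emitter subregion."""
    psf = PSFModel(SIGMA_PSF)
    base = Subregion(np.zeros((16, 16)), pad=pad)
    lam = np.full((16, 16), BACKGROUND_OFFSET)
    for x, y in zip(FIVE_EMITTER_X, FIVE_EMITTER_Y):
        lam += emitter_pixel_counts(x, y, INTENSITY, psf, base)
    data = np.random.default_rng(seed).poisson(lam)
    return Subregion(data.astype(float), pad=pad)


def blinking_calibration_priors(
    seed: int, rho: float, region_width: float
) -> PriorSet:
    """Priors estimated by the single-emitter pass on sparse blinking data.

    The calibration movie has isolated emitters switching with the standard
    kinetics, so the fitted intensities include partial-exposure frames --
    the realistic breadth of an empirically estimated intensity prior.
    """
    movie, _ = simulate(
        SimConfig(
            frame_size=32, n_frames=40, structure="uniform", rho=30.0,
            k_on=0.02, k_off=K_OFF, intensity=INTENSITY,
            background=BACKGROUND_OFFSET, sigma_psf=SIGMA_PSF, seed=seed,
        )
    )
    return estimate_priors(
        movie, PSFModel(SIGMA_PSF), rho=rho, region_width=region_width
    )


def matched_intensity_priors(
    seed: int, rho: float, region_width: float
) -> PriorSet:
    """Priors matched to constantly-on emitters of one nominal intensity.

    Used for the two-emitter study, where the emitters never blink and the
    single-emitter pass cannot be run on the (heavily overlapped) study
    data itself; the calibration movie holds isolated, constantly-on
    emitters of the same intensity.
    """
    movie, _ = simulate(
        SimConfig(
            frame_size=32, n_frames=30, structure="uniform", rho=1.2,
            always_on=True, intensity=INTENSITY,
            background=BACKGROUND_OFFSET, sigma_psf=SIGMA_PSF, seed=seed,
        )
    )
    return estimate_priors(
        movie, PSFModel(SIGMA_PSF), rho=rho, region_width=region_width
    )


def tuned_within_model_acceptance(seed: int) -> float:
    """Within-model acceptance (%) of a tuned post-burn-in chain.

    Protocol: simulate the standard five-emitter subregion, auto-tune the
    proposal scales, run the standard burn-in + post chain and divide the
    accepted within-model moves of the post phase by the attempted ones.
    """
    psf = PSFModel(SIGMA_PSF)
    region = five_emitter_region(seed)
    priors = blinking_calibration_priors(seed + 1, rho=5.0 / 256, region_width=16)
    scales = tune_scales(
        region, psf, priors, ProposalScales(),
        rng_seed=np.random.default_rng([seed, 101]),
    )
    _, post = run_chain(region, psf, priors, JumpSchedule(), scales, seed)
    return 100.0 * post.acceptance_fraction(classes=("in_model",))


def circle_standard_error_mode(
    seed: int, n_frames: int = 200, radius_sigma: float = 0.833
) -> float:
    """Mode (px) of the localization standard errors on the circle phantom.

    Protocol: emitters at 1,000 per um of circumference on a circle of
    radius ``radius_sigma * sigma_PSF`` in a 10x10 px frame, blinking to an
    average of 4.5 on-emitters per frame; run the full pipeline and take
    the mode of the returned x/y standard errors in 0.01-px bins.
    """
    frame = 10
    target_on = 4.5
    cfg = SimConfig(
        frame_size=frame, n_frames=n_frames, structure="circle",
        circle_radius=radius_sigma * SIGMA_PSF, rho=1000.0, border=0.0,
        k_off=K_OFF, k_on=0.01, intensity=INTENSITY,
        background=BACKGROUND_OFFSET, sigma_psf=SIGMA_PSF, seed=seed,
    )
    # the emitter count is a Poisson draw; placement depends only on the
    # seed, so re-simulating with the solved k_on keeps the same positions
    _, truth0 = simulate(cfg)
    cfg.k_on = solve_kon(len(truth0), target_on, K_OFF)
    movie, _ = simulate(cfg)
    priors = blinking_calibration_priors(
        seed + 1, rho=target_on / frame**2, region_width=frame
    )
    config = RunConfig(rho=target_on / frame**2)
    result = run_fit(movie, config=config, priors=priors, seed=seed)
    se = np.concatenate([
        result.table["se_x_px"].to_numpy(), result.table["se_y_px"].to_numpy()
    ])
    bins = np.arange(0.0, config.max_se + 0.01, 0.01)
    hist, edges = np.histogram(se, bins=bins)
    return float(edges[hist.argmax()] + 0.005)


def two_emitter_resolution(
    seed: int,
    separations=None,
    frames_per_sep: int = 50,
    burnin_jumps: int = 3000,
    post_jumps: int = 1500,
) -> tuple[float, "pandas.DataFrame"]:
    """Smallest resolved separation (sigma_PSF units) for two emitters.

    Protocol: for each separation simulate constantly-on 2,000-photon
    emitter pairs, fit every frame with a matched intensity prior, and
    report the smallest separation whose MAPN-equals-2 fraction exceeds
    one half.
    """
    from .evaluate import resolution_curve

    if separations is None:
        separations = np.round(np.arange(0.10, 1.5001, 0.05), 3)
    frame = 10
    psf = PSFModel(SIGMA_PSF)
    priors = matched_intensity_priors(seed + 1, rho=2.0 / frame**2, region_width=frame)
    schedule = JumpSchedule(burnin_jumps=burnin_jumps, post_jumps=post_jumps)
    counter = {"i": 0}

    def fitter(movie, sim_cfg):
        counter["i"] += 1
        return fit_frame_counts(
            movie, psf, priors, schedule=schedule,
            seed=seed * 1000 + counter["i"],
        )

    curve = resolution_curve(
        fitter, separations, photons=INTENSITY, frames_per_sep=frames_per_sep,
        rng=seed, sigma_psf=SIGMA_PSF, background=BACKGROUND_OFFSET,
        frame_size=frame,
    )
    return curve.attrs["resolution_threshold"], curve
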