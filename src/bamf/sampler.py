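"""Trans-dimensional sampler over emitter models.

The chain explores states that differ in the number of emitters via four
reversible jump pairs -- (birth, death), (split, merge), (generalized
split, generalized merge) and label conversion -- plus three within-model
moves (single-emitter, correlated group, background plane).  Acceptance is
Metropolis-Hastings-Green: each jump proposal carries the log of

    q(reverse) / q(forward) * |Jacobian of the dimension-matching map|

(the "Green factor"); the engine adds the log-posterior difference and the
ratio of the move-class probabilities of the current phase, which need not
be symmetric between a pair.

Every proposal builder comes in a deterministic form (state + the random
numbers it would have drawn) so that reversibility and detailed balance can
be checked pointwise, plus a random wrapper used by the engine.

Direction convention for the generalized pair (the internal one used by the
schedule): ``g_split`` *gathers* photons from up to K nearby emitters into
one new emitter (dimension +3); ``g_merge`` deletes an emitter and
*scatters* its photons over its nearby emitters (dimension -3).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .model import (
    BACKGROUND,
    SIGNAL,
    BackgroundPlane,
    EmitterSet,
    ModelState,
    PSFModel,
    PriorSet,
    Subregion,
    log_posterior,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MOVE_CLASSES",
    "JumpSchedule",
    "ProposalScales",
    "ChainSample",
    "Chain",
    "run_chain",
    "tune_scales",
]

MOVE_CLASSES = (
    "in_model",
    "birth",
    "death",
    "split",
    "merge",
    "g_split",
    "g_merge",
    "conversion",
)
_REVERSE_CLASS = {
    "in_model": "in_model",
    "birth": "death",
    "death": "birth",
    "split": "merge",
    "merge": "split",
    "g_split": "g_merge",
    "g_merge": "g_split",
    "conversion": "conversion",
}

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

# kernel constants for the generalized jumps
K_NEIGHBORS = 4       # at most K donors / donees
F_MAX = 0.5           # largest intensity fraction taken from one donor
R_MERGE_SIGMA = 2.0   # merge pairing radius, units of sigma_PSF
R_GROUP_SIGMA = 3.0   # generalized-jump neighborhood radius, units of sigma_PSF


@dataclass
class JumpSchedule:
    """Move-class probabilities and chain lengths for both phases.

    Defaults are the standard settings: burn-in
    (0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1) over
    (in-model, birth, death, split, merge, g-split, g-merge, conversion)
    for 3,000 jumps, then (0.4, 0.05, 0.05, 0, 0, 0.15, 0.15, 0.2) for
    2,000 jumps.  Dense data typically needs 20,000 / 10,000 jumps.
    """

    burnin_probs: tuple = (0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1)
    post_probs: tuple = (0.4, 0.05, 0.05, 0.0, 0.0, 0.15, 0.15, 0.2)
    burnin_jumps: int = 3000
    post_jumps: int = 2000

    def __post_init__(self):
        for name, p in (("burnin", self.burnin_probs), ("post", self.post_probs)):
            p = np.asarray(p, dtype=float)
            if len(p) != len(MOVE_CLASSES) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
                raise ValueError(f"{name} probabilities must be a length-8 simplex vector")
            # guard: a jump whose reverse class can never be proposed would
            # break reversibility
            for i, cls in enumerate(MOVE_CLASSES):
                j = MOVE_CLASSES.index(_REVERSE_CLASS[cls])
                if p[i] > 0 and p[j] == 0:
                    raise ValueError(
                        f"{name} phase proposes {cls} but its reverse "
                        f"{_REVERSE_CLASS[cls]} has zero probability"
                    )

    def probs(self, phase: str) -> np.ndarray:
        return np.asarray(
            self.burnin_probs if phase == "burnin" else self.post_probs, dtype=float
        )

    def jumps(self, phase: str) -> int:
        return self.burnin_jumps if phase == "burnin" else self.post_jumps

    @classmethod
    def dense(cls) -> "JumpSchedule":
        return cls(burnin_jumps=20000, post_jumps=10000)


@dataclass
class ProposalScales:
    """Widths of the zero-mean normal within-model proposal kernels."""

    sigma_xy: float = 0.075   # pixels (tuned within 0.05--0.1)
    sigma_I: float = 7.5      # photons (tuned within 5--10)
    sigma_b: float = 1.0      # photons
    sigma_slope: float = 0.05  # photons/pixel per pixel

    def __post_init__(self):
        if min(self.sigma_xy, self.sigma_I, self.sigma_b, self.sigma_slope) <= 0:
            raise ValueError("proposal scales must be > 0")

    def copy(self) -> "ProposalScales":
        return ProposalScales(self.sigma_xy, self.sigma_I, self.sigma_b, self.sigma_slope)


@dataclass
class ChainSample:
    state: ModelState
    jump_type: str
    accepted: bool
    log_posterior: float


@dataclass
class Chain:
    """Ordered record of every jump of one phase."""

    samples: list = field(default_factory=list)
    seed: Optional[int] = None
    phase: str = "post"

    def __len__(self):
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def last_state(self) -> ModelState:
        return self.samples[-1].state

    def n_signal_trace(self) -> np.ndarray:
        return np.array([s.state.emitters.n_signal for s in self.samples], dtype=int)

    def acceptance_fraction(self, classes: Optional[Sequence[str]] = None) -> float:
        sel = [
            s for s in self.samples if classes is None or s.jump_type in classes
        ]
        if not sel:
            return np.nan
        return sum(s.accepted for s in sel) / len(sel)

    def to_frame(self):
        """Columnar per-jump bookkeeping (phase, type, accepted, N, logpost)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "phase": self.phase,
                "jump_type": [s.jump_type for s in self.samples],
                "accepted": [s.accepted for s in self.samples],
                "n_emitters": [len(s.state.emitters) for s in self.samples],
                "n_signal": [s.state.emitters.n_signal for s in self.samples],
                "log_posterior": [s.log_posterior for s in self.samples],
            }
        )


# ---------------------------------------------------------------------------
# state surgery helpers
# ---------------------------------------------------------------------------


def _with_emitters(state: ModelState, x, y, I, label) -> ModelState:
    return ModelState(
        EmitterSet._fast(
            np.asarray(x, float), np.asarray(y, float), np.asarray(I, float),
            np.asarray(label, np.int8),
        ),
        state.background.copy(),
    )


def _append_emitter(state: ModelState, x, y, I, label) -> ModelState:
    em = state.emitters
    return _with_emitters(
        state,
        np.append(em.x, x),
        np.append(em.y, y),
        np.append(em.I, I),
        np.append(em.label, np.int8(label)),
    )


def _delete_emitters(state: ModelState, idx) -> ModelState:
    em = state.emitters
    return _with_emitters(
        state,
        np.delete(em.x, idx),
        np.delete(em.y, idx),
        np.delete(em.I, idx),
        np.delete(em.label, idx),
    )


def _log_normal_pdf(z: float, sigma: float) -> float:
    return -0.5 * (z / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI


def _qualifying_pairs(state: ModelState, r_merge: float) -> list[tuple[int, int]]:
    """Same-label emitter pairs within the merge radius."""
    em = state.emitters
    n = len(em)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if em.label[i] != em.label[j]:
                continue
            if np.hypot(em.x[i] - em.x[j], em.y[i] - em.y[j]) <= r_merge:
                pairs.append((i, j))
    return pairs


def _neighbor_set(state: ModelState, center_idx: int, r_group: float,
                  include_self: bool) -> list[int]:
    """Up to K nearest *signal* emitters within r_group of a signal emitter."""
    em = state.emitters
    d = np.hypot(em.x - em.x[center_idx], em.y - em.y[center_idx])
    cand = [
        i
        for i in np.argsort(d, kind="stable")
        if em.label[i] == SIGNAL and d[i] <= r_group and (include_self or i != center_idx)
    ]
    return cand[:K_NEIGHBORS]


# ---------------------------------------------------------------------------
# deterministic jump builders: (state, drawn randoms) -> (new state, log Green)
# ---------------------------------------------------------------------------


def build_birth(state: ModelState, x: float, y: float, I: float,
                region: Subregion, priors: PriorSet):
    """Birth of a signal emitter at (x, y) with intensity I.

    The position and intensity proposal densities are exactly the priors,
    so they cancel in the acceptance against the prior of the new emitter;
    the Green factor keeps the bookkeeping explicit:
    ``q_rev = 1/(N+1)`` (death picks the emitter), ``q_fwd = p_sig(I)/A``.
    """
    n = len(state.emitters)
    new = _append_emitter(state, x, y, I, SIGNAL)
    log_green = (
        -np.log(n + 1)
        + np.log(region.support_area)
        - float(priors.log_signal_I(I)[0])
    )
    return new, log_green


def build_death(state: ModelState, idx: int, region: Subregion, priors: PriorSet):
    """Death of emitter ``idx``; exact reciprocal of the matching birth.

    Only signal emitters can die (births only create signal emitters, so
    removing a background kernel would have no reverse move).
    """
    em = state.emitters
    if em.label[idx] != SIGNAL:
        return None
    n = len(em)
    log_green = (
        float(priors.log_signal_I(em.I[idx])[0])
        - np.log(region.support_area)
        + np.log(n)
    )
    return _delete_emitters(state, idx), log_green


def build_split(state: ModelState, idx: int, u: float, dx: float, dy: float,
                psf: PSFModel):
    """Split emitter ``idx`` into two, preserving the intensity-weighted centroid.

    ``I1 = u I``, ``I2 = (1-u) I``; ``x1 = x + (1-u) dx``, ``x2 = x - u dx``
    (same in y).  The Jacobian of the dimension-matching map is ``I``.
    """
    em = state.emitters
    x, y, I, lab = em.x[idx], em.y[idx], em.I[idx], em.label[idx]
    x1, y1, I1 = x + (1 - u) * dx, y + (1 - u) * dy, u * I
    x2, y2, I2 = x - u * dx, y - u * dy, (1 - u) * I
    if I1 <= 0 or I2 <= 0:
        return None
    sigma_split = psf.sigma
    d = np.hypot(dx, dy)
    if d > R_MERGE_SIGMA * psf.sigma:
        return None  # the reverse merge could never pick this pair
    new = _delete_emitters(state, idx)
    new = _append_emitter(new, x1, y1, I1, lab)
    new = _append_emitter(new, x2, y2, I2, lab)
    n_pairs_new = len(_qualifying_pairs(new, R_MERGE_SIGMA * psf.sigma))
    n = len(em)
    log_q_fwd = (
        -np.log(n)
        + _log_normal_pdf(dx, sigma_split)
        + _log_normal_pdf(dy, sigma_split)
    )
    log_q_rev = -np.log(n_pairs_new)
    log_green = log_q_rev - log_q_fwd + np.log(I)
    return new, log_green


def build_merge(state: ModelState, i: int, j: int, psf: PSFModel):
    """Merge emitters i, j into their intensity-weighted centroid."""
    em = state.emitters
    if em.label[i] != em.label[j]:
        return None
    dx, dy = em.x[i] - em.x[j], em.y[i] - em.y[j]
    if np.hypot(dx, dy) > R_MERGE_SIGMA * psf.sigma:
        return None
    I_m = em.I[i] + em.I[j]
    u = em.I[i] / I_m
    x_m = (em.I[i] * em.x[i] + em.I[j] * em.x[j]) / I_m
    y_m = (em.I[i] * em.y[i] + em.I[j] * em.y[j]) / I_m
    n_pairs = len(_qualifying_pairs(state, R_MERGE_SIGMA * psf.sigma))
    new = _delete_emitters(state, [i, j])
    new = _append_emitter(new, x_m, y_m, I_m, em.label[i])
    sigma_split = psf.sigma
    log_q_fwd = -np.log(n_pairs)
    log_q_rev = (
        -np.log(len(new.emitters))
        + _log_normal_pdf(dx, sigma_split)
        + _log_normal_pdf(dy, sigma_split)
    )
    log_green = log_q_rev - log_q_fwd - np.log(I_m)
    return new, log_green


def build_gather(state: ModelState, focal: int, us: np.ndarray, ex: float,
                 ey: float, psf: PSFModel):
    """Generalized split: photons from up to K emitters make a new emitter.

    Donors are the <=K nearest signal emitters within the group radius of
    the focal emitter (the focal itself included).  Donor j gives the
    fraction ``us[j] ~ U(0, F_MAX)`` of its photons; the new emitter sits at
    the photon-weighted donor centroid plus Gaussian jitter.  Jacobian:
    ``prod(I_donors) / I_new**(m-1)``.
    """
    em = state.emitters
    if em.label[focal] != SIGNAL:
        return None
    r_group = R_GROUP_SIGMA * psf.sigma
    donors = _neighbor_set(state, focal, r_group, include_self=True)
    m = len(donors)
    us = np.asarray(us, float)
    if len(us) != m or np.any(us <= 0) or np.any(us >= F_MAX):
        return None
    I_d = em.I[donors]
    T = us * I_d
    I_new = float(T.sum())
    xc = float((T * em.x[donors]).sum() / I_new)
    yc = float((T * em.y[donors]).sum() / I_new)
    x_new, y_new = xc + ex, yc + ey
    new = state.copy()
    new.emitters.I[donors] = I_d - T
    new = _append_emitter(new, x_new, y_new, I_new, SIGNAL)
    # reverse feasibility: scattering the new emitter must select exactly
    # the donor set as donees
    new_idx = len(new.emitters) - 1
    donees_rev = _neighbor_set(new, new_idx, r_group, include_self=False)
    if set(donees_rev) != set(donors):
        return None
    n_sig = em.n_signal
    # forward selection: any signal emitter whose donor set equals this one
    n_focal = sum(
        1
        for c in donors
        if set(_neighbor_set(state, c, r_group, include_self=True)) == set(donors)
    )
    sj = psf.sigma
    log_q_fwd = (
        np.log(n_focal) - np.log(n_sig)
        - m * np.log(F_MAX)
        + _log_normal_pdf(ex, sj)
        + _log_normal_pdf(ey, sj)
    )
    log_q_rev = -np.log(n_sig + 1) + gammaln(m)  # uniform Dirichlet density (m-1)!
    log_jac = float(np.sum(np.log(I_d))) - (m - 1) * np.log(I_new)
    return new, log_q_rev - log_q_fwd + log_jac


def build_scatter(state: ModelState, idx: int, v: np.ndarray, psf: PSFModel):
    """Generalized merge: delete emitter ``idx`` and distribute its photons
    over its <=K nearest signal neighbors with Dirichlet weights ``v``."""
    em = state.emitters
    if em.label[idx] != SIGNAL:
        return None
    r_group = R_GROUP_SIGMA * psf.sigma
    donees = _neighbor_set(state, idx, r_group, include_self=False)
    m = len(donees)
    if m == 0:
        return None
    v = np.asarray(v, float)
    if len(v) != m or np.any(v <= 0) or abs(v.sum() - 1) > 1e-9:
        return None
    I_e = em.I[idx]
    dI = v * I_e
    I_after = em.I[donees] + dI
    # reverse (gather) reconstruction: u_j = dI_j / I_after_j must respect F_MAX
    us = dI / I_after
    if np.any(us >= F_MAX):
        return None
    xc = float((dI * em.x[donees]).sum() / I_e)
    yc = float((dI * em.y[donees]).sum() / I_e)
    ex, ey = em.x[idx] - xc, em.y[idx] - yc
    new = state.copy()
    new.emitters.I[donees] = I_after
    new = _delete_emitters(new, idx)
    # map donee indices into the post-deletion state
    donees_new = [d - 1 if d > idx else d for d in donees]
    # reverse feasibility: some focal in the new state must yield this donor set
    n_focal_rev = sum(
        1
        for c in donees_new
        if set(_neighbor_set(new, c, r_group, include_self=True)) == set(donees_new)
    )
    if n_focal_rev == 0:
        return None
    n_sig = em.n_signal
    sj = psf.sigma
    log_q_fwd = -np.log(n_sig) + gammaln(m)
    log_q_rev = (
        np.log(n_focal_rev) - np.log(n_sig - 1)
        - m * np.log(F_MAX)
        + _log_normal_pdf(ex, sj)
        + _log_normal_pdf(ey, sj)
    )
    log_jac = (m - 1) * np.log(I_e) - float(np.sum(np.log(I_after)))
    return new, log_q_rev - log_q_fwd + log_jac


def build_conversion(state: ModelState, idx: int, priors: Optional[PriorSet] = None,
                     new_I: Optional[float] = None):
    """Flip the signal/background label of one emitter (dimension unchanged).

    With ``new_I=None`` only the label flips: the proposal is symmetric,
    the Green factor is zero, and the acceptance ratio reduces to the
    intensity-prior density ratio of the two labels (the likelihood does
    not see labels).  With ``new_I`` drawn from the destination label's
    intensity prior the proposal densities cancel against the priors and
    the acceptance becomes the pure likelihood ratio -- this variant lets
    an emitter escape a label whose intensity prior no longer supports its
    current intensity.
    """
    new = state.copy()
    lab = new.emitters.label
    to_signal = lab[idx] == BACKGROUND
    lab[idx] = SIGNAL if to_signal else BACKGROUND
    if new_I is None:
        return new, 0.0
    if new_I <= 0:
        return None
    I_old = state.emitters.I[idx]
    new.emitters.I[idx] = new_I
    if to_signal:
        log_q_fwd = float(priors.log_signal_I(new_I)[0])
        log_q_rev = float(priors.log_background_I(I_old)[0])
    else:
        log_q_fwd = float(priors.log_background_I(new_I)[0])
        log_q_rev = float(priors.log_signal_I(I_old)[0])
    return new, log_q_rev - log_q_fwd


# ---------------------------------------------------------------------------
# within-model moves (all symmetric: Green factor 0)
# ---------------------------------------------------------------------------


def move_single(state: ModelState, scales: ProposalScales, rng: np.random.Generator):
    """Perturb one emitter's position and intensity; background move if N=0."""
    n = len(state.emitters)
    if n == 0:
        return move_background(state, scales, rng)
    idx = int(rng.integers(n))
    new = state.copy()
    new.emitters.x[idx] += scales.sigma_xy * rng.standard_normal()
    new.emitters.y[idx] += scales.sigma_xy * rng.standard_normal()
    new.emitters.I[idx] += scales.sigma_I * rng.standard_normal()
    return new, 0.0


def move_group(state: ModelState, scales: ProposalScales, psf: PSFModel,
               rng: np.random.Generator):
    """Common shift of a close group plus an intensity exchange within it.

    The group is the chosen emitter and every emitter within 2 sigma_PSF of
    it; the exchange transfers a normal increment between a random pair, so
    the group's total intensity is conserved exactly.  Falls back to a
    single-emitter move when the chosen emitter is isolated.
    """
    em = state.emitters
    n = len(em)
    if n == 0:
        return move_background(state, scales, rng)
    idx = int(rng.integers(n))
    d = np.hypot(em.x - em.x[idx], em.y - em.y[idx])
    group = np.nonzero(d <= 2.0 * psf.sigma)[0]
    if len(group) < 2:
        return move_single(state, scales, rng)
    new = state.copy()
    shift_x = scales.sigma_xy * rng.standard_normal()
    shift_y = scales.sigma_xy * rng.standard_normal()
    new.emitters.x[group] += shift_x
    new.emitters.y[group] += shift_y
    i, j = rng.choice(group, size=2, replace=False)
    dI = scales.sigma_I * rng.standard_normal()
    new.emitters.I[i] += dI
    new.emitters.I[j] -= dI
    return new, 0.0


def move_background(state: ModelState, scales: ProposalScales,
                    rng: np.random.Generator):
    """Perturb the tilted-plane background parameters."""
    new = state.copy()
    new.background.b += scales.sigma_b * rng.standard_normal()
    new.background.a_x += scales.sigma_slope * rng.standard_normal()
    new.background.a_y += scales.sigma_slope * rng.standard_normal()
    return new, 0.0


# ---------------------------------------------------------------------------
# random proposal wrappers
# ---------------------------------------------------------------------------


def _propose(cls: str, state: ModelState, region: Subregion, psf: PSFModel,
             priors: PriorSet, scales: ProposalScales, rng: np.random.Generator):
    em = state.emitters
    n = len(em)
    if cls == "in_model":
        which = rng.integers(3)
        if which == 0:
            return move_single(state, scales, rng)
        if which == 1:
            return move_group(state, scales, psf, rng)
        return move_background(state, scales, rng)
    if cls == "birth":
        (x0, x1), (y0, y1) = region.xlim, region.ylim
        x = rng.uniform(x0, x1)
        y = rng.uniform(y0, y1)
        I = float(priors.signal_intensity.sample(rng, 1)[0])
        return build_birth(state, x, y, I, region, priors)
    if cls == "death":
        if n == 0:
            return None
        return build_death(state, int(rng.integers(n)), region, priors)
    if cls == "split":
        if n == 0:
            return None
        idx = int(rng.integers(n))
        u = rng.uniform()
        dx = psf.sigma * rng.standard_normal()
        dy = psf.sigma * rng.standard_normal()
        return build_split(state, idx, u, dx, dy, psf)
    if cls == "merge":
        pairs = _qualifying_pairs(state, R_MERGE_SIGMA * psf.sigma)
        if not pairs:
            return None
        i, j = pairs[rng.integers(len(pairs))]
        return build_merge(state, i, j, psf)
    if cls == "g_split":
        sig = np.nonzero(em.label == SIGNAL)[0]
        if len(sig) == 0:
            return None
        focal = int(sig[rng.integers(len(sig))])
        donors = _neighbor_set(state, focal, R_GROUP_SIGMA * psf.sigma, True)
        us = rng.uniform(0, F_MAX, size=len(donors))
        ex = psf.sigma * rng.standard_normal()
        ey = psf.sigma * rng.standard_normal()
        return build_gather(state, focal, us, ex, ey, psf)
    if cls == "g_merge":
        sig = np.nonzero(em.label == SIGNAL)[0]
        if len(sig) == 0:
            return None
        idx = int(sig[rng.integers(len(sig))])
        donees = _neighbor_set(state, idx, R_GROUP_SIGMA * psf.sigma, False)
        if not donees:
            return None
        v = rng.dirichlet(np.ones(len(donees)))
        return build_scatter(state, idx, v, psf)
    if cls == "conversion":
        if n == 0:
            return None
        idx = int(rng.integers(n))
        if rng.uniform() < 0.5:  # label flip only
            return build_conversion(state, idx)
        # flip plus intensity redraw from the destination prior
        if em.label[idx] == BACKGROUND:
            new_I = float(priors.signal_intensity.sample(rng, 1)[0])
        else:
            new_I = float(priors.sample_background_I(rng, 1)[0])
        return build_conversion(state, idx, priors, new_I)
    raise ValueError(f"unknown move class {cls!r}")


def _run_phase(
    phase: str,
    n_jumps: int,
    state: ModelState,
    lp: float,
    region: Subregion,
    psf: PSFModel,
    priors: PriorSet,
    schedule: JumpSchedule,
    scales: ProposalScales,
    rng: np.random.Generator,
    record: bool = True,
) -> tuple[Chain, ModelState, float]:
    probs = schedule.probs(phase)
    chain = Chain(phase=phase)
    rev_idx = [MOVE_CLASSES.index(_REVERSE_CLASS[c]) for c in MOVE_CLASSES]
    with np.errstate(divide="ignore"):
        log_class_ratio = [
            np.log(probs[rev_idx[i]]) - np.log(probs[i]) if probs[i] > 0 else 0.0
            for i in range(len(MOVE_CLASSES))
        ]
    classes = rng.choice(len(MOVE_CLASSES), size=n_jumps, p=probs)
    for c in classes:
        cls = MOVE_CLASSES[c]
        result = _propose(cls, state, region, psf, priors, scales, rng)
        accepted = False
        if result is not None:
            new_state, log_green = result
            lp_new = log_posterior(new_state, psf, region, priors)
            if np.isfinite(lp_new):
                log_alpha = (lp_new - lp) + log_green + log_class_ratio[c]
                if log_alpha >= 0 or np.log(rng.uniform()) < log_alpha:
                    state, lp = new_state, lp_new
                    accepted = True
        if record:
            chain.samples.append(ChainSample(state, cls, accepted, lp))
    return chain, state, lp


def initial_state(region: Subregion) -> ModelState:
    """Empty model with the plane offset at the mean observed count."""
    return ModelState.background_only(max(float(region.data.mean()), 0.1))


def run_chain(
    region: Subregion,
    psf: PSFModel,
    priors: PriorSet,
    schedule: JumpSchedule,
    scales: ProposalScales,
    rng_seed,
    init_state: Optional[ModelState] = None,
) -> tuple[Chain, Chain]:
    """Run the burn-in then post-burn-in chain on one subregion.

    The chain starts from an empty (background-only) model: the burn-in
    phase's high between-model jump probability is what discovers emitters.
    The post chain continues from the burn-in chain's last state.  Chains
    are bitwise reproducible given the seed.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    state = init_state.copy() if init_state is not None else initial_state(region)
    lp = log_posterior(state, psf, region, priors)
    if not np.isfinite(lp):
        raise ValueError("initial state has zero posterior probability")
    burnin, state, lp = _run_phase(
        "burnin", schedule.burnin_jumps, state, lp, region, psf, priors,
        schedule, scales, rng,
    )
    post, state, lp = _run_phase(
        "post", schedule.post_jumps, state, lp, region, psf, priors,
        schedule, scales, rng,
    )
    seed_val = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    burnin.seed = post.seed = seed_val
    return burnin, post


def tune_scales(
    region: Subregion,
    psf: PSFModel,
    priors: PriorSet,
    scales0: ProposalScales,
    target_band: tuple[float, float] = (0.25, 0.50),
    schedule: Optional[JumpSchedule] = None,
    pilot_jumps: int = 400,
    max_rounds: int = 15,
    rng_seed=0,
) -> ProposalScales:
    """Adapt position/intensity proposal widths to the acceptance band.

    Short pilot chains are run and ``sigma_xy`` and ``sigma_I`` multiplied
    or divided by 1.5 until the within-model acceptance fraction lies in
    the target band (default 25--50%) or the round budget is exhausted.
    Adaptation happens entirely before any recorded phase, so the recorded
    chains keep detailed balance.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    schedule = schedule or JumpSchedule()
    scales = scales0.copy()
    state = initial_state(region)
    lp = log_posterior(state, psf, region, priors)
    lo, hi = target_band
    # discovery pilot: let the trans-dimensional moves populate the model
    # first, so acceptance is measured in the regime that matters
    _, state, lp = _run_phase(
        "burnin", 4 * pilot_jumps, state, lp, region, psf, priors,
        schedule, scales, rng, record=False,
    )
    # measurement pilots propose within-model moves only: every jump
    # contributes to the estimate and the model order stays put
    pilot_schedule = JumpSchedule(
        burnin_probs=(1.0, 0, 0, 0, 0, 0, 0, 0),
        post_probs=(1.0, 0, 0, 0, 0, 0, 0, 0),
        burnin_jumps=pilot_jumps,
        post_jumps=0,
    )
    for _ in range(max_rounds):
        chain, state, lp = _run_phase(
            "burnin", pilot_jumps, state, lp, region, psf, priors,
            pilot_schedule, scales, rng,
        )
        rate = chain.acceptance_fraction(classes=("in_model",))
        if np.isnan(rate):
            break
        if lo <= rate <= hi:
            return scales
        factor = 1.5 if rate > hi else 1 / 1.5
        scales = ProposalScales(
            sigma_xy=scales.sigma_xy * factor,
            sigma_I=scales.sigma_I * factor,
            sigma_b=scales.sigma_b,
            sigma_slope=scales.sigma_slope,
        )
    warnings.warn(
        "proposal-scale tuning did not reach the target acceptance band; "
        "returning the last scales",
        stacklevel=2,
    )
    return scales
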