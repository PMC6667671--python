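"""Bayesian (QUEST-style) adaptive threshold estimation.

A discrete posterior over candidate thresholds T is maintained on a grid of
the working intensity scale.  The psychometric function is the Watson-Pelli
Weibull

    psi(x - T) = gamma + (1 - gamma - delta) * (1 - exp(-10**(beta * (x - T + eps))))

where gamma is the guess rate (0.5 for 2AFC), delta the lapse rate, beta the
slope, and eps an internal offset chosen so that psi(0) equals the targeted
proportion correct (default 0.75).  T is therefore directly the intensity
estimated to yield the target accuracy, and placing the next trial at the
posterior mode of T is the classic QUEST placement rule.

Two usage modes are supported:

* trial-to-trial: ``update`` after each response, ``recommend`` before each
  trial (standard QUEST);
* block-to-block: intensity held fixed within a block and re-estimated
  between blocks by ``threshold_from_trials`` on a trailing window of
  (intensity, correct) pairs — because updates are pointwise products, this
  batch rebuild is identical to sequential updating on the same trials.

Thresholds live on a task-specific working scale described by
``IntensityRule``: percent morph distance (rounded to the nearest 2%, capped
at 100%) for the face-identity task, or log10 nRMS-contrast difference
(uncapped rounding-free, capped at 0 so the linear threshold stays <= 1) for
the contrast task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PsychometricSpec",
    "IntensityRule",
    "StaircaseState",
    "init",
    "update",
    "recommend",
    "threshold_from_trials",
    "gaussian_prior",
    "MORPH_RULE",
    "LOG_CONTRAST_RULE",
    "IDENTITY_SPEC",
    "CONTRAST_SPEC",
]


@dataclass(frozen=True)
class PsychometricSpec:
    """Weibull psychometric parameters on the staircase's working scale."""

    beta: float
    delta: float = 0.05
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not 0 <= self.delta < 0.5:
            raise ValueError("delta must lie in [0, 0.5)")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")

    def epsilon(self, target_p: float) -> float:
        """Offset placing the target proportion correct at x - T = 0."""
        ceiling = 1.0 - self.gamma - self.delta
        frac = (target_p - self.gamma) / ceiling
        if not 0 < frac < 1:
            raise ValueError(f"target_p={target_p} unreachable for this psychometric")
        return math.log10(-math.log1p(-frac)) / self.beta

    def p_correct(self, x, T, target_p: float = 0.75):
        """psi(x - T): probability of a correct response at intensity x."""
        d = np.asarray(x, dtype=float) - np.asarray(T, dtype=float) + self.epsilon(target_p)
        ceiling = 1.0 - self.gamma - self.delta
        return self.gamma + ceiling * -np.expm1(-(10.0 ** (self.beta * d)))


# Printed psychometric parameters of the two experiment types: a shallow
# slope on the percent-morph scale for the identity task, a conventional
# slope on the log-contrast scale for the contrast task.
IDENTITY_SPEC = PsychometricSpec(beta=0.1, delta=0.05, gamma=0.5)
CONTRAST_SPEC = PsychometricSpec(beta=3.5, delta=0.05, gamma=0.5)


@dataclass(frozen=True)
class IntensityRule:
    """Mapping from raw threshold estimates to presentable stimulus intensity.

    ``quantize`` rounds to the task's step (2% morph increments; none for
    log contrast) and clips to [floor, cap].  The two stimulus alternatives
    are generated at midpoint +/- intensity / 2 on the linearised scale.
    """

    kind: str  # "morph" or "log_contrast"
    midpoint: float
    step: float | None = None
    cap: float | None = None
    floor: float | None = None

    def quantize(self, x: float) -> float:
        v = float(x)
        if self.step is not None:
            v = round(v / self.step) * self.step
        if self.cap is not None:
            v = min(v, self.cap)
        if self.floor is not None:
            v = max(v, self.floor)
        return v

    def linear_difference(self, intensity: float) -> float:
        """Physical A-B difference on the linearised stimulus scale."""
        if self.kind == "log_contrast":
            return 10.0 ** intensity
        return intensity

    def stimulus_pair(self, intensity: float) -> tuple[float, float]:
        half = self.linear_difference(intensity) / 2.0
        return (self.midpoint - half, self.midpoint + half)


MORPH_RULE = IntensityRule(kind="morph", midpoint=50.0, step=2.0, cap=100.0, floor=2.0)
LOG_CONTRAST_RULE = IntensityRule(kind="log_contrast", midpoint=0.5, cap=0.0)


def gaussian_prior(grid: np.ndarray, center: float, sd: float) -> np.ndarray:
    """Normalised Gaussian prior mass over a threshold grid."""
    p = np.exp(-0.5 * ((np.asarray(grid) - center) / sd) ** 2)
    return p / p.sum()


@dataclass(frozen=True)
class StaircaseState:
    """Posterior over candidate thresholds plus the trial history behind it."""

    grid: np.ndarray
    prior: np.ndarray
    posterior: np.ndarray
    spec: PsychometricSpec
    target_p: float = 0.75
    rule: IntensityRule | None = None
    history: tuple[tuple[float, bool], ...] = field(default_factory=tuple)

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.posterior))])

    @property
    def mean(self) -> float:
        return float(np.dot(self.grid, self.posterior))

    def quantile(self, q: float) -> float:
        cdf = np.cumsum(self.posterior)
        return float(self.grid[int(np.searchsorted(cdf, q))])


def init(
    grid: np.ndarray,
    prior: np.ndarray | None = None,
    spec: PsychometricSpec = IDENTITY_SPEC,
    target_p: float = 0.75,
    rule: IntensityRule | None = None,
) -> StaircaseState:
    """Create a staircase with a normalised prior and empty history."""
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    if prior is None:
        prior = np.full(grid.size, 1.0 / grid.size)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != grid.shape:
        raise ValueError("prior and grid shapes differ")
    if np.any(prior < 0) or prior.sum() <= 0:
        raise ValueError("prior must be nonnegative with positive total mass")
    prior = prior / prior.sum()
    spec.epsilon(target_p)  # validate reachability up front
    return StaircaseState(
        grid=grid, prior=prior, posterior=prior.copy(), spec=spec,
        target_p=target_p, rule=rule,
    )


def _likelihood(state: StaircaseState, intensity: float, correct: bool) -> np.ndarray:
    p = state.spec.p_correct(intensity, state.grid, state.target_p)
    return p if correct else 1.0 - p


def update(state: StaircaseState, intensity: float, correct: bool) -> StaircaseState:
    """Bayesian update with one (intensity, correct) observation."""
    post = state.posterior * _likelihood(state, float(intensity), bool(correct))
    total = post.sum()
    if total <= 0:  # numerically impossible data; keep previous posterior
        post = state.posterior.copy()
        total = post.sum()
    return replace(
        state,
        posterior=post / total,
        history=state.history + ((float(intensity), bool(correct)),),
    )


def recommend(state: StaircaseState, estimator: str = "mode") -> float:
    """Next intensity to present: a posterior summary passed through the
    intensity rule's quantisation (if a rule is attached)."""
    if estimator == "mode":
        raw = state.mode
    elif estimator == "mean":
        raw = state.mean
    elif estimator == "median":
        raw = state.quantile(0.5)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return state.rule.quantize(raw) if state.rule is not None else raw


def threshold_from_trials(
    trials,
    spec: PsychometricSpec = IDENTITY_SPEC,
    grid: np.ndarray | None = None,
    prior: np.ndarray | None = None,
    target_p: float = 0.75,
) -> float:
    """Posterior-mode threshold rebuilt from scratch on a set of trials.

    ``trials`` is an iterable of (intensity, correct) pairs.  Because the
    posterior is a pointwise product of per-trial likelihoods, this equals
    the final posterior of a staircase that saw the same trials sequentially
    from the same prior.  Used for offline per-block (20-trial) and
    per-staircase (40-trial) threshold estimates, and for the trailing-80
    block-to-block updates.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("threshold_from_trials requires at least one trial")
    if grid is None:
        grid = np.linspace(1.0, 100.0, 201)
    state = init(grid, prior, spec, target_p)
    logpost = np.log(state.prior)
    x = np.array([t[0] for t in trials], dtype=float)
    c = np.array([bool(t[1]) for t in trials])
    p = spec.p_correct(x[:, None], state.grid[None, :], target_p)
    like = np.where(c[:, None], p, 1.0 - p)
    logpost = logpost + np.sum(np.log(np.clip(like, 1e-300, None)), axis=0)
    return float(state.grid[int(np.argmax(logpost))])
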