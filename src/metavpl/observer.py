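"""Synthetic observers with perceptual-learning dynamics.

An observer transduces a physical stimulus difference (percent morph
distance, or linear nRMS-contrast difference) into an internal separation
M = gain * difference and then behaves as the dual-stage SDT model: a
stage-1 Gaussian draw (SD sigma_I) decides the response, and the same draw
plus stage-2 noise (SD sigma_II) drives the confidence rating.

Learning is an exponential decay of sigma_I over cumulative training blocks,

    sigma_I(t) = sigma_end + (sigma_start - sigma_end) * exp(-t / tau),

the simplest monotone saturating trajectory.  Three scenarios are built in:

* ``identity``  — sigma_I shrinks, sigma_II stays constant, so the ratio
  sigma_II / sigma_I grows and metacognitive accuracy falls even though the
  staircase clamps objective accuracy (the face-identity pattern);
* ``contrast``  — sigma_II shrinks proportionally with sigma_I, so both the
  clamped objective accuracy and metacognitive accuracy stay flat (the
  face-contrast pattern);
* ``static``    — no learning at all (null model for false-positive checks).

Untrained conditions are only seen before and after training; their sigma_I
improvement is the trained improvement scaled by a transfer fraction in
[0, 1].

Confidence ratings are quartile-calibrated against a running window (default
200 trials per condition) of recent confidence-variable magnitudes, seeded
analytically from the current parameters until the window has enough trials;
this keeps the four ratings roughly equally used as the staircase moves the
stimulus around, mimicking an observer who spreads responses over the whole
scale.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

from . import protocol
from .quest import (
    CONTRAST_SPEC,
    IDENTITY_SPEC,
    LOG_CONTRAST_RULE,
    MORPH_RULE,
    IntensityRule,
    PsychometricSpec,
)

__all__ = [
    "ObserverSpec",
    "SDTObserver",
    "WeibullObserver",
    "ExperimentConfig",
    "simulate_experiment",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ObserverSpec:
    """Generative parameters and learning schedule of a synthetic subject.

    ``gain`` maps physical stimulus difference to internal separation M.
    ``tau`` is the learning time constant in cumulative training blocks
    (12 per day).  ``sigma2_mode`` selects the scenario coupling of
    confidence noise to decision noise.  ``transfer`` is the fraction of the
    sigma_I improvement that untrained conditions inherit.
    """

    gain: float
    sigma_start: float = 1.0
    sigma_end: float = 1.0
    tau: float = 8.0
    sigma2_start: float = 1.0
    sigma2_mode: str = "constant"  # "constant" or "proportional"
    transfer: float = 0.67
    calibration_window: int = 200
    min_calibration: int = 40
    scenario: str = "custom"

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be > 0")
        if not (self.sigma_start > 0 and self.sigma_end > 0):
            raise ValueError("sigma_I schedule endpoints must be > 0")
        if self.sigma2_start < 0:
            raise ValueError("sigma2_start must be >= 0")
        if not 0 <= self.transfer <= 1:
            raise ValueError("transfer must lie in [0, 1]")
        if self.sigma2_mode not in ("constant", "proportional"):
            raise ValueError("sigma2_mode must be 'constant' or 'proportional'")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")

    # -- learning schedules ---------------------------------------------------

    def sigma_I(self, t: float, trained: bool = True) -> float:
        """Stage-1 noise after t cumulative training blocks."""
        s = self.sigma_end + (self.sigma_start - self.sigma_end) * np.exp(-t / self.tau)
        if trained:
            return float(s)
        return float(self.sigma_start - self.transfer * (self.sigma_start - s))

    def sigma_II(self, t: float, trained: bool = True) -> float:
        """Stage-2 noise after t cumulative training blocks."""
        if self.sigma2_mode == "constant":
            return self.sigma2_start
        return self.sigma2_start * self.sigma_I(t, trained) / self.sigma_start

    # -- scenario factories ---------------------------------------------------
    # Learning defaults give a ~45% drop in sigma_I (hence in threshold) over
    # the 36 training blocks at a near-constant *relative* rate (the floor
    # sits well below the 3-day range), so the staircase's tracking lag is
    # steady and clamped Type-I accuracy shows no day trend; partial transfer
    # matches set-invariant learning.

    @classmethod
    def identity_vpl(cls, **kw) -> "ObserverSpec":
        base = dict(gain=0.045, sigma_start=1.0, sigma_end=0.1, tau=52.0,
                    sigma2_start=0.85, sigma2_mode="constant", scenario="identity")
        base.update(kw)
        return cls(**base)

    @classmethod
    def contrast_vpl(cls, **kw) -> "ObserverSpec":
        base = dict(gain=10.0, sigma_start=1.0, sigma_end=0.1, tau=60.0,
                    sigma2_start=1.0, sigma2_mode="proportional", scenario="contrast")
        base.update(kw)
        return cls(**base)

    @classmethod
    def static(cls, kind: str = "identity", **kw) -> "ObserverSpec":
        gain = 0.045 if kind == "identity" else 10.0
        base = dict(gain=gain, sigma_start=1.0, sigma_end=1.0, tau=8.0,
                    sigma2_start=1.0, sigma2_mode="constant", scenario="static")
        base.update(kw)
        return cls(**base)


def _quartiles(a: np.ndarray) -> np.ndarray:
    # linear-interpolation quartiles; np.quantile's overhead dominates the
    # per-trial loop for these small calibration buffers
    a = np.sort(a)
    n = a.size
    out = np.empty(3)
    for k, q in enumerate((0.25, 0.5, 0.75)):
        h = (n - 1) * q
        i = int(h)
        j = min(i + 1, n - 1)
        out[k] = a[i] + (h - i) * (a[j] - a[i])
    return out


def _folded_mixture_quantiles(M: float, s: float) -> np.ndarray:
    """25/50/75th percentiles of |X|, X an equal mixture of N(+-M/2, s)."""
    def cdf(x):
        return ndtr((x - M / 2) / s) + ndtr((x + M / 2) / s) - 1.0

    hi = M / 2 + 8 * s
    return np.array([brentq(lambda x, q=q: cdf(x) - q, 0.0, hi) for q in (0.25, 0.5, 0.75)])


class SDTObserver:
    """Stateful dual-stage SDT responder driven by the staircase protocol.

    Stage-1 draws (and the true alternative) come from one RNG stream and
    stage-2 confidence noise from another, so two observers reset with the
    same seed but different sigma_II produce identical response/correctness
    sequences and differ only in ratings.
    """

    def __init__(self, spec: ObserverSpec, rule: IntensityRule = MORPH_RULE):
        self.spec = spec
        self.rule = rule
        self.reset(0)

    def reset(self, seed) -> None:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        c1, c2 = ss.spawn(2)
        self._rng1 = np.random.default_rng(c1)
        self._rng2 = np.random.default_rng(c2)
        self._calib: dict[str, deque] = {}

    # -- internals -------------------------------------------------------------

    def _params_at(self, intensity: float, t: float, trained: bool):
        diff = self.rule.linear_difference(intensity)
        if diff <= 0:
            raise ValueError(f"stimulus difference must be positive, got {diff}")
        M = self.spec.gain * diff
        return M, self.spec.sigma_I(t, trained), self.spec.sigma_II(t, trained)

    def _boundaries(self, condition: str, M: float, s_total: float) -> np.ndarray:
        buf = self._calib.get(condition)
        if buf is None or len(buf) < self.spec.min_calibration:
            return _folded_mixture_quantiles(M, s_total)
        return _quartiles(np.asarray(buf))

    def _record_calibration(self, condition: str, magnitudes: np.ndarray) -> None:
        buf = self._calib.setdefault(
            condition, deque(maxlen=self.spec.calibration_window)
        )
        buf.extend(np.atleast_1d(magnitudes))

    def p_correct(self, intensity: float, t: float = 0.0, trained: bool = True) -> float:
        """Analytic accuracy Phi(M / (2 sigma_I)) at a given intensity."""
        M, s1, _ = self._params_at(intensity, t, trained)
        return float(ndtr(M / (2 * s1)))

    def threshold_75(self, t: float = 0.0, trained: bool = True) -> float:
        """Intensity at which accuracy is 75% (on the working scale)."""
        d_star = 2 * 0.6744897501960817  # 2 * Phi^-1(0.75)
        diff = d_star * self.spec.sigma_I(t, trained) / self.spec.gain
        if self.rule.kind == "log_contrast":
            return float(np.log10(diff))
        return float(diff)

    # -- protocol interface ------------------------------------------------------

    def respond_block(self, condition: str, intensity: float, t: float,
                      trained: bool, n: int):
        """Simulate n trials at one fixed intensity (vectorised).

        Confidence boundaries are refreshed once at block start from the
        running calibration window; the window is then extended with the
        block's trials.  Returns arrays (true_a, resp_a, correct, confidence).
        """
        M, s1, s2 = self._params_at(intensity, t, trained)
        true_a = self._rng1.random(n) < 0.5
        internal = np.where(true_a, M / 2, -M / 2) + s1 * self._rng1.standard_normal(n)
        conf_var = internal + s2 * self._rng2.standard_normal(n)
        resp_a = internal >= 0.0
        correct = resp_a == true_a
        bounds = self._boundaries(condition, M, float(np.hypot(s1, s2)))
        mag = np.abs(conf_var)
        conf = 1 + (mag > bounds[0]).astype(int) + (mag > bounds[1]) + (mag > bounds[2])
        self._record_calibration(condition, mag)
        return true_a, resp_a, correct, conf

    def respond(self, condition: str, intensity: float, t: float, trained: bool):
        """One trial; returns (true_alt, response, correct, confidence)."""
        ta, ra, co, cf = self.respond_block(condition, intensity, t, trained, 1)
        return ("A" if ta[0] else "B", "A" if ra[0] else "B", bool(co[0]), int(cf[0]))


class WeibullObserver:
    """Observer whose accuracy follows a Weibull psychometric exactly.

    Used to validate staircase convergence against an observer that matches
    the staircase's own response model; confidence is uninformative (uniform).
    """

    def __init__(self, threshold: float, spec: PsychometricSpec,
                 target_p: float = 0.75, rule: IntensityRule = MORPH_RULE):
        self.threshold = threshold
        self.spec = spec
        self.target_p = target_p
        self.rule = rule
        self.reset(0)

    def reset(self, seed) -> None:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        self._rng = np.random.default_rng(ss)

    def respond_block(self, condition, intensity, t, trained, n):
        p = float(self.spec.p_correct(intensity, self.threshold, self.target_p))
        true_a = self._rng.random(n) < 0.5
        correct = self._rng.random(n) < p
        resp_a = np.where(correct, true_a, ~true_a)
        conf = self._rng.integers(1, 5, size=n)
        return true_a, resp_a, correct, conf

    def respond(self, condition, intensity, t, trained):
        ta, ra, co, cf = self.respond_block(condition, intensity, t, trained, 1)
        return ("A" if ta[0] else "B", "A" if ra[0] else "B", bool(co[0]), int(cf[0]))


@dataclass(frozen=True)
class ExperimentConfig:
    """Counts and staircase settings of the 3-day training design.

    Day 1: pre-training (2 blocks, each one 40-trial trial-to-trial staircase
    per condition, all four conditions interleaved) then 12 training blocks
    of 20 fixed-intensity trials per trained condition.  Days 2-3: 2 baseline
    blocks (40 trial-to-trial trials per trained condition) then 12 training
    blocks; Day 3 ends with post-training (mirror of pre-training).
    Block-to-block threshold updates use the trailing ``window`` trials of
    each condition.
    """

    kind: str = "identity"
    trained: tuple[str, str] = ("set1_a", "set1_b")
    untrained: tuple[str, str] = ("set2_a", "set2_b")
    days: int = 3
    training_blocks_per_day: int = 12
    trials_per_block: int = 20  # per trained condition
    window: int = 80
    staircase_trials: int = 40  # per pre/post staircase
    baseline_blocks: int = 2
    baseline_trials: int = 40  # per trained condition per baseline block
    spec: PsychometricSpec = IDENTITY_SPEC
    rule: IntensityRule = MORPH_RULE
    grid_points: int = 201
    prior_center: float = 35.0
    prior_sd: float = 15.0
    target_p: float = 0.75

    def __post_init__(self) -> None:
        if set(self.trained) & set(self.untrained):
            raise ValueError("trained and untrained condition sets must be disjoint")
        for n in (self.days, self.training_blocks_per_day, self.trials_per_block,
                  self.window, self.staircase_trials, self.baseline_blocks,
                  self.baseline_trials, self.grid_points):
            if n <= 0:
                raise ValueError("all design counts must be positive")

    @property
    def grid(self) -> np.ndarray:
        if self.kind == "identity":
            return np.linspace(1.0, 100.0, self.grid_points)
        return np.linspace(-3.0, 0.0, self.grid_points)

    @classmethod
    def identity(cls, **kw) -> "ExperimentConfig":
        return cls(kind="identity", spec=IDENTITY_SPEC, rule=MORPH_RULE,
                   prior_center=35.0, prior_sd=15.0, **kw)

    @classmethod
    def contrast(cls, **kw) -> "ExperimentConfig":
        return cls(kind="contrast", spec=CONTRAST_SPEC, rule=LOG_CONTRAST_RULE,
                   prior_center=-0.8, prior_sd=0.5, **kw)


def default_observer(config: ExperimentConfig, scenario: str) -> SDTObserver:
    """Scenario observer matched to a config's stimulus scale."""
    if scenario == "identity":
        spec = ObserverSpec.identity_vpl()
    elif scenario == "contrast":
        spec = ObserverSpec.contrast_vpl()
    elif scenario == "static":
        spec = ObserverSpec.static(kind=config.kind)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return SDTObserver(spec, rule=config.rule)


def simulate_experiment(
    observer, config: ExperimentConfig, seed: int = 0, subject: str = "s01"
) -> pd.DataFrame:
    """Full 3-day trial table for one subject (deterministic given seed)."""
    return protocol.run_blockwise_protocol(observer, config, seed, subject=subject)


def simulate_cohort(
    n_subjects: int,
    base_spec: ObserverSpec,
    config: ExperimentConfig,
    seed: int = 0,
    cv: float = 0.2,
) -> tuple[list[pd.DataFrame], dict]:
    """Simulate a cohort of independent subjects.

    Per-subject gain and noise scale get multiplicative log-normal jitter
    with coefficient of variation ``cv`` around the base spec (the
    sigma_end / sigma_start ratio, i.e. the relative learning effect, is
    preserved).  Trained-set assignment is counterbalanced: even-indexed
    subjects train on ``config.trained``, odd-indexed on ``config.untrained``.

    Returns the per-subject trial tables and a manifest of drawn parameters
    and seeds.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects + 1)[1:]]
    sigma_lognorm = np.sqrt(np.log1p(cv**2))

    tables: list[pd.DataFrame] = []
    manifest: dict = {"seed": seed, "cv": cv, "subjects": {}}
    for i in range(n_subjects):
        jg, js = np.exp(param_rng.normal(-sigma_lognorm**2 / 2, sigma_lognorm, size=2)) \
            if cv > 0 else (1.0, 1.0)
        spec_i = replace(
            base_spec,
            gain=base_spec.gain * jg,
            sigma_start=base_spec.sigma_start * js,
            sigma_end=base_spec.sigma_end * js,
            sigma2_start=base_spec.sigma2_start * js,
        )
        if i % 2 == 0:
            cfg_i = config
        else:  # swap trained/untrained sets
            cfg_i = replace(config, trained=config.untrained, untrained=config.trained)
        sid = f"s{i + 1:02d}"
        obs = SDTObserver(spec_i, rule=config.rule)
        tables.append(simulate_experiment(obs, cfg_i, seed=subject_seeds[i], subject=sid))
        manifest["subjects"][sid] = {
            "seed": subject_seeds[i],
            "gain": spec_i.gain,
            "sigma_start": spec_i.sigma_start,
            "sigma_end": spec_i.sigma_end,
            "sigma2_start": spec_i.sigma2_start,
            "sigma2_mode": spec_i.sigma2_mode,
            "transfer": spec_i.transfer,
            "trained_set": list(cfg_i.trained),
        }
    return tables, manifest
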