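"""Single- and dual-stage signal-detection observer models.

The generative model: on each 2AFC trial the observer receives an internal
response drawn from a Gaussian centred at +M/2 (alternative A) or -M/2
(alternative B) with common standard deviation sigma_I, and responds "A"
whenever the internal response exceeds an unbiased criterion at zero.
Confidence is read from a second variable — the internal response plus
optional stage-2 Gaussian noise of SD sigma_II — by cutting the pooled
absolute distance from the criterion at its empirical 25th/50th/75th
percentiles, so each rating 1-4 is used on 25% of trials by construction.
sigma_II = 0 recovers the single-stage model in which decisions and
confidence share one signal; sigma_II > 0 is the dual-stage model in which
confidence inherits the decision signal plus extra noise.

Decision accuracy depends only on d' = M / sigma_I (Type-I AUC is
Phi(d'/sqrt(2)) in closed form); metacognitive accuracy additionally depends
on sigma_II / sigma_I, which is what lets the dual-stage model dissociate
Type-II from Type-I performance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import pearsonr, spearmanr

from .roc import type1_auc_from_arrays, type2_auc_from_arrays

__all__ = [
    "ModelParams",
    "SimulatedCondition",
    "AUCSurface",
    "simulate_condition",
    "type1_auc_closed_form",
    "solve_m_for_type1",
    "type2_at_fixed_type1",
    "compute_surface",
    "correlate_surfaces",
    "signal_enhancement_variant",
    "confidence_boundaries",
    "assign_ratings",
]

DEFAULT_N_PER_ALT = 5000


@dataclass(frozen=True)
class ModelParams:
    """Generative parameters of the (dual-stage) SDT observer.

    Parameters
    ----------
    M : float
        Separation between the means of the two internal-response
        distributions (internal-response units); A sits at +M/2, B at -M/2.
    sigma_I : float
        Stage-1 (decision) noise SD. Must be positive.
    sigma_II : float
        Stage-2 (confidence) noise SD; 0 gives the single-stage model.
    criterion : float
        Perceptual decision criterion; the model assumes an unbiased
        observer, so this is 0 unless explicitly overridden.
    n_per_alt : int
        Simulated trials per alternative (>= 4 so confidence quartiles exist).
    """

    M: float
    sigma_I: float = 1.0
    sigma_II: float = 0.0
    criterion: float = 0.0
    n_per_alt: int = DEFAULT_N_PER_ALT

    def __post_init__(self) -> None:
        if not self.M >= 0:
            raise ValueError(f"M must be >= 0, got {self.M}")
        if not self.sigma_I > 0:
            raise ValueError(f"sigma_I must be > 0, got {self.sigma_I}")
        if not self.sigma_II >= 0:
            raise ValueError(f"sigma_II must be >= 0, got {self.sigma_II}")
        if self.n_per_alt < 4:
            raise ValueError("n_per_alt must be >= 4 so rating quartiles exist")


@dataclass(frozen=True)
class SimulatedCondition:
    """One simulated condition: parameters, seed and the generated trials."""

    params: ModelParams
    seed: int
    trials: pd.DataFrame

    @property
    def proportion_correct(self) -> float:
        return float(self.trials["correct"].mean())

    @property
    def type1_auc(self) -> float:
        return type1_auc_from_arrays(
            (self.trials["true_alt"] == "A").to_numpy(),
            (self.trials["response"] == "A").to_numpy(),
            self.trials["confidence"].to_numpy(),
        )

    @property
    def type2_auc(self) -> float:
        return type2_auc_from_arrays(
            self.trials["correct"].to_numpy(),
            self.trials["confidence"].to_numpy(),
        )


@dataclass(frozen=True)
class AUCSurface:
    """Type-I and Type-II AUC over an (M, sigma_I) parameter grid."""

    M_levels: np.ndarray
    sigma_levels: np.ndarray
    sigma_II: float
    type1: np.ndarray  # shape (len(sigma_levels), len(M_levels))
    type2: np.ndarray
    seed: int
    n_per_alt: int

    def to_frame(self) -> pd.DataFrame:
        """Flat table with one row per grid cell."""
        mm, ss = np.meshgrid(self.M_levels, self.sigma_levels)
        return pd.DataFrame(
            {
                "M": mm.ravel(),
                "sigma_I": ss.ravel(),
                "sigma_II": self.sigma_II,
                "type1_auc": self.type1.ravel(),
                "type2_auc": self.type2.ravel(),
            }
        )


def _stage_rngs(seed) -> tuple[np.random.Generator, np.random.Generator]:
    # Separate streams for stage-1 and stage-2 noise so that changing
    # sigma_II with a fixed seed leaves every perceptual response intact.
    ss = np.random.SeedSequence(seed)
    c1, c2 = ss.spawn(2)
    return np.random.default_rng(c1), np.random.default_rng(c2)


def confidence_boundaries(conf_var: np.ndarray, criterion: float = 0.0) -> np.ndarray:
    """25th/50th/75th percentiles of |confidence variable - criterion|."""
    return np.quantile(np.abs(conf_var - criterion), [0.25, 0.5, 0.75])


def assign_ratings(
    conf_var: np.ndarray, boundaries: np.ndarray, criterion: float = 0.0
) -> np.ndarray:
    """Map confidence-variable magnitudes to ratings 1-4 by quartile membership.

    Values exactly on a boundary take the lower rating.
    """
    a = np.abs(conf_var - criterion)
    return 1 + (a > boundaries[0]).astype(int) + (a > boundaries[1]) + (a > boundaries[2])


def _simulate_arrays(params: ModelParams, rng1, rng2):
    n = params.n_per_alt
    true_a = np.zeros(2 * n, dtype=bool)
    true_a[:n] = True
    mu = np.where(true_a, params.M / 2.0, -params.M / 2.0)
    internal = mu + params.sigma_I * rng1.standard_normal(2 * n)
    conf_var = internal + params.sigma_II * rng2.standard_normal(2 * n)
    resp_a = internal >= params.criterion  # tie at criterion -> respond A
    correct = resp_a == true_a
    conf = assign_ratings(
        conf_var, confidence_boundaries(conf_var, params.criterion), params.criterion
    )
    return true_a, internal, conf_var, resp_a, correct, conf


def simulate_condition(params: ModelParams, seed: int = 0) -> SimulatedCondition:
    """Simulate one condition of 2 * n_per_alt confidence-rated trials.

    Ratings are cut at the empirical quartiles of |confidence variable|
    pooled over both alternatives of this condition, so every rating occurs
    on 25% of trials up to integer rounding.
    """
    rng1, rng2 = _stage_rngs(seed)
    true_a, internal, conf_var, resp_a, correct, conf = _simulate_arrays(
        params, rng1, rng2
    )
    trials = pd.DataFrame(
        {
            "true_alt": np.where(true_a, "A", "B"),
            "internal": internal,
            "conf_var": conf_var,
            "response": np.where(resp_a, "A", "B"),
            "correct": correct,
            "confidence": conf,
        }
    )
    return SimulatedCondition(params=params, seed=seed, trials=trials)


def type1_auc_closed_form(M: float, sigma_I: float) -> float:
    """Equal-variance Gaussian ROC area, Phi(M / (sigma_I * sqrt(2))).

    Analytic counterpart of the simulated Type-I AUC; also the basis for
    threshold solving, since stage-2 noise leaves Type-I performance
    untouched.
    """
    if not sigma_I > 0:
        raise ValueError(f"sigma_I must be > 0, got {sigma_I}")
    if M < 0:
        raise ValueError(f"M must be >= 0, got {M}")
    return float(ndtr(M / (sigma_I * np.sqrt(2.0))))


def solve_m_for_type1(
    target_auc: float,
    sigma_I: float,
    *,
    tolerance: float = 1e-10,
) -> float:
    """Mean separation M at which Type-I AUC equals ``target_auc``.

    Inverts the closed form: M = sigma_I * sqrt(2) * Phi^-1(target).  Valid
    for targets strictly between 0.5 and 1 (at 0.5 only M = 0 works and the
    problem degenerates; 1.0 is unreachable).
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target Type-I AUC must lie strictly between 0.5 and 1")
    if not sigma_I > 0:
        raise ValueError(f"sigma_I must be > 0, got {sigma_I}")
    m = float(sigma_I * np.sqrt(2.0) * ndtri(target_auc))
    assert abs(type1_auc_closed_form(m, sigma_I) - target_auc) < max(tolerance, 1e-12)
    return m


def type2_at_fixed_type1(
    target_type1: float,
    sigma_I: float = 1.0,
    sigma_II: float = 0.0,
    n_per_alt: int = DEFAULT_N_PER_ALT,
    seed: int = 0,
) -> float:
    """Simulated Type-II AUC at the M that yields a given Type-I AUC.

    With sigma_II = 0 the result depends on the target alone (scale
    invariance in M / sigma_I), e.g. about 0.68 at a Type-I AUC of 0.8.
    """
    m = solve_m_for_type1(target_type1, sigma_I)
    cond = simulate_condition(
        ModelParams(M=m, sigma_I=sigma_I, sigma_II=sigma_II, n_per_alt=n_per_alt),
        seed=seed,
    )
    return cond.type2_auc


def compute_surface(
    M_levels: np.ndarray | None = None,
    sigma_levels: np.ndarray | None = None,
    sigma_II: float = 0.0,
    n_per_alt: int = DEFAULT_N_PER_ALT,
    seed: int = 0,
) -> AUCSurface:
    """Simulate Type-I and Type-II AUC over an (M, sigma_I) grid.

    Defaults reproduce the reference grid: 65 M levels from 0 to 6.5 by 65
    sigma_I levels from 0.5 to 2 (4225 cells).  These ranges jointly
    reproduce the canonical surface correlations (about 0.99 single-stage
    and 0.97/0.93/0.89 at sigma_II = 0.5/0.75/1); the dual-stage values in
    particular are sensitive to the sigma_I range, since it sets the spread
    of sigma_II / sigma_I across the grid.  Each cell gets its own
    deterministic child seed of ``seed``, so cells are mutually independent
    and the whole surface is reproducible.  Cells whose Type-II AUC is
    undefined (no errors simulated) are stored as NaN.
    """
    if M_levels is None:
        M_levels = np.linspace(0.0, 6.5, 65)
    if sigma_levels is None:
        sigma_levels = np.linspace(0.5, 2.0, 65)
    M_levels = np.asarray(M_levels, dtype=float)
    sigma_levels = np.asarray(sigma_levels, dtype=float)
    for name, g in (("M_levels", M_levels), ("sigma_levels", sigma_levels)):
        if g.size == 0 or (g.size > 1 and not np.all(np.diff(g) > 0)):
            raise ValueError(f"{name} must be non-empty and strictly increasing")
    if np.any(sigma_levels <= 0):
        raise ValueError("sigma_levels must be positive")

    n_cells = M_levels.size * sigma_levels.size
    children = np.random.SeedSequence(seed).spawn(n_cells)
    t1 = np.empty((sigma_levels.size, M_levels.size))
    t2 = np.empty_like(t1)
    k = 0
    for i, sig in enumerate(sigma_levels):
        for j, m in enumerate(M_levels):
            c1, c2 = children[k].spawn(2)
            rng1, rng2 = np.random.default_rng(c1), np.random.default_rng(c2)
            params = ModelParams(M=m, sigma_I=sig, sigma_II=sigma_II, n_per_alt=n_per_alt)
            true_a, _, _, resp_a, correct, conf = _simulate_arrays(params, rng1, rng2)
            t1[i, j] = type1_auc_from_arrays(true_a, resp_a, conf)
            t2[i, j] = type2_auc_from_arrays(correct, conf)
            k += 1
    return AUCSurface(
        M_levels=M_levels,
        sigma_levels=sigma_levels,
        sigma_II=float(sigma_II),
        type1=t1,
        type2=t2,
        seed=seed,
        n_per_alt=n_per_alt,
    )


def correlate_surfaces(surface: AUCSurface, method: str = "pearson") -> float:
    """Correlation between Type-I and Type-II AUC over all defined grid cells."""
    t1 = surface.type1.ravel()
    t2 = surface.type2.ravel()
    ok = ~(np.isnan(t1) | np.isnan(t2))
    if ok.sum() < 2:
        raise ValueError("correlation undefined: fewer than 2 defined cells")
    t1, t2 = t1[ok], t2[ok]
    if np.ptp(t1) == 0 or np.ptp(t2) == 0:
        raise ValueError("correlation undefined: constant surface")
    if method == "pearson":
        return float(pearsonr(t1, t2).statistic)
    if method == "spearman":
        return float(spearmanr(t1, t2).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def signal_enhancement_variant(baseline: ModelParams, M_gain: float) -> ModelParams:
    """Model variant in which learning scales the signal M instead of
    shrinking sigma_I.

    Type-I performance depends on M / sigma_I only, so a gain of g is
    Type-I-equivalent to dividing sigma_I by g; the variants differ in how
    confidence behaves once sigma_II is fixed in absolute units.
    """
    if not M_gain > 0:
        raise ValueError(f"M_gain must be > 0, got {M_gain}")
    return replace(baseline, M=baseline.M * M_gain)
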