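"""Non-parametric rating-ROC analysis of confidence-rated 2AFC trials.

Objective accuracy is measured as the area under the Type-I ROC curve:
trials where the true alternative is A are treated as signal-present, trials
where it is B as signal-absent, and the response criterion is swept across
the 8 ordered response categories (respond-A with confidence 4 down to 1,
then respond-B with confidence 1 up to 4), giving 7 interior ROC points.

Metacognitive accuracy is the area under the Type-II ROC curve: correct
trials are signal-present, incorrect trials signal-absent, and the criterion
is swept over confidence ratings 4, 3, 2, giving 3 interior points.

Both areas are computed by the trapezoidal rule over the curve anchored at
(0, 0) and (1, 1).  For the Type-I curve this is algebraically identical to
the ties-adjusted Mann-Whitney concordance statistic on the 8-level ordinal
score.  Degenerate inputs (no signal trials, no incorrect trials) yield NaN
rather than a fabricated chance value, so that downstream averages are not
biased toward 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RatingROC",
    "ConfidenceSummary",
    "type1_roc",
    "type2_roc",
    "auc",
    "confidence_summary",
    "type1_auc_from_arrays",
    "type2_auc_from_arrays",
]

N_RATINGS = 4


@dataclass(frozen=True)
class RatingROC:
    """An anchored rating ROC curve.

    Attributes
    ----------
    points : ndarray, shape (k + 2, 2)
        (false-alarm rate, hit rate) pairs from (0, 0) to (1, 1), criterion
        loosening left to right.
    kind : str
        ``"type1"`` (7 interior points) or ``"type2"`` (3 interior points).
    """

    points: np.ndarray
    kind: str
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "auc", auc(pts))

    @property
    def interior_points(self) -> np.ndarray:
        return self.points[1:-1]


@dataclass(frozen=True)
class ConfidenceSummary:
    """Mean/variance of confidence ratings split by response correctness.

    Variances use the sample (n - 1) denominator; a class with no trials has
    NaN mean and variance, a single-trial class has NaN variance.
    """

    mean_correct: float
    mean_incorrect: float
    var_correct: float
    var_incorrect: float
    n_correct: int
    n_incorrect: int


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under an anchored ROC curve.

    Points must run from (0, 0) to (1, 1) with non-decreasing coordinates;
    duplicate points are allowed (zero-width segments).
    """
    pts = np.asarray(points, dtype=float)
    fa, hit = pts[:, 0], pts[:, 1]
    if not (np.all(np.diff(fa) >= -1e-12) and np.all(np.diff(hit) >= -1e-12)):
        raise ValueError("ROC points must be non-decreasing in both coordinates")
    if not (fa[0] == 0 and hit[0] == 0 and fa[-1] == 1 and hit[-1] == 1):
        raise ValueError("ROC curve must be anchored at (0,0) and (1,1)")
    return float(np.trapezoid(hit, fa))


def _require_columns(trials: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise KeyError(f"trial table lacks columns {missing}")


def type1_roc(trials: pd.DataFrame) -> RatingROC:
    """Type-I rating ROC from a confidence-rated trial table.

    Expects columns ``true_alt`` (``"A"``/``"B"``), ``response``
    (``"A"``/``"B"``) and ``confidence`` (1-4).

    Raises
    ------
    ValueError
        If either alternative is absent (the ROC is undefined; callers that
        need a soft failure should catch this and record NaN).
    """
    _require_columns(trials, ("true_alt", "response", "confidence"))
    is_a = (trials["true_alt"] == "A").to_numpy()
    resp_a = (trials["response"] == "A").to_numpy()
    conf = trials["confidence"].to_numpy(dtype=int)
    if not is_a.any() or is_a.all():
        raise ValueError("Type-I ROC undefined: need both X=A and X=B trials")
    cat = _type1_categories(resp_a, conf)
    counts_sig = np.bincount(cat[is_a], minlength=2 * N_RATINGS)
    counts_noise = np.bincount(cat[~is_a], minlength=2 * N_RATINGS)
    return RatingROC(_cumulative_curve(counts_sig, counts_noise), kind="type1")


def type2_roc(trials: pd.DataFrame) -> RatingROC:
    """Type-II rating ROC: discriminating correct from incorrect trials.

    Expects columns ``correct`` (bool) and ``confidence`` (1-4).  Hit rate is
    P(confidence >= c | correct), false-alarm rate P(confidence >= c |
    incorrect), for c = 4, 3, 2.

    Raises
    ------
    ValueError
        If all trials are correct or all incorrect.
    """
    _require_columns(trials, ("correct", "confidence"))
    correct = trials["correct"].to_numpy(dtype=bool)
    conf = trials["confidence"].to_numpy(dtype=int)
    if correct.all() or not correct.any():
        raise ValueError("Type-II ROC undefined: need both correct and incorrect trials")
    counts_sig = np.bincount(conf[correct] - 1, minlength=N_RATINGS)[::-1]
    counts_noise = np.bincount(conf[~correct] - 1, minlength=N_RATINGS)[::-1]
    return RatingROC(_cumulative_curve(counts_sig, counts_noise), kind="type2")


def confidence_summary(trials: pd.DataFrame) -> ConfidenceSummary:
    """Per-correctness mean and sample variance of confidence ratings."""
    _require_columns(trials, ("correct", "confidence"))
    if len(trials) == 0:
        raise ValueError("empty trial set")
    correct = trials["correct"].to_numpy(dtype=bool)
    conf = trials["confidence"].to_numpy(dtype=float)

    def _stats(x: np.ndarray) -> tuple[float, float]:
        if x.size == 0:
            return (np.nan, np.nan)
        if x.size == 1:
            return (float(x[0]), np.nan)
        return (float(x.mean()), float(x.var(ddof=1)))

    mc, vc = _stats(conf[correct])
    mi, vi = _stats(conf[~correct])
    return ConfidenceSummary(mc, mi, vc, vi, int(correct.sum()), int((~correct).sum()))


# -- array fast paths ---------------------------------------------------------
# Used by the parameter-grid simulations, where building a DataFrame per grid
# cell would dominate runtime.  NaN is returned (not raised) for degenerate
# cells so vectorised sweeps can record them as missing.


def _type1_categories(resp_a: np.ndarray, conf: np.ndarray) -> np.ndarray:
    # Ordered most-confident-A (0) ... most-confident-B (7).
    return np.where(resp_a, N_RATINGS - conf, N_RATINGS - 1 + conf)


def _cumulative_curve(counts_sig: np.ndarray, counts_noise: np.ndarray) -> np.ndarray:
    hit = np.concatenate([[0.0], np.cumsum(counts_sig) / counts_sig.sum()])
    fa = np.concatenate([[0.0], np.cumsum(counts_noise) / counts_noise.sum()])
    return np.column_stack([fa, hit])


def type1_auc_from_arrays(
    true_a: np.ndarray, resp_a: np.ndarray, conf: np.ndarray
) -> float:
    """Type-I AUC from boolean/int arrays; NaN if one alternative is absent."""
    if not true_a.any() or true_a.all():
        return float("nan")
    cat = _type1_categories(resp_a, conf)
    cs = np.bincount(cat[true_a], minlength=2 * N_RATINGS)
    cn = np.bincount(cat[~true_a], minlength=2 * N_RATINGS)
    return float(np.trapezoid(*_anchored(cs, cn)))


def type2_auc_from_arrays(correct: np.ndarray, conf: np.ndarray) -> float:
    """Type-II AUC from boolean/int arrays; NaN if correctness is constant."""
    if correct.all() or not correct.any():
        return float("nan")
    cs = np.bincount(conf[correct] - 1, minlength=N_RATINGS)[::-1]
    cn = np.bincount(conf[~correct] - 1, minlength=N_RATINGS)[::-1]
    return float(np.trapezoid(*_anchored(cs, cn)))


def _anchored(counts_sig: np.ndarray, counts_noise: np.ndarray):
    hit = np.concatenate([[0.0], np.cumsum(counts_sig) / counts_sig.sum()])
    fa = np.concatenate([[0.0], np.cumsum(counts_noise) / counts_noise.sum()])
    return hit, fa
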