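"""End-to-end analysis of staircase-clamped training experiments.

Per training block (20 fixed-intensity trials per condition) five measure
families are computed: the QUEST posterior-mode threshold, Type-I AUC,
Type-II AUC, and the mean and variance of confidence ratings split by
correctness.  Pre/post staircase thresholds give percent threshold
improvement and the transfer index TI = improvement_untrained /
improvement_trained (1 = complete transfer of learning to the untrained
set, 0 = none).  Cohort-level statistics are: one-tailed Wilcoxon
signed-rank tests of post < pre thresholds per condition set, one-tailed
one-sample t-tests of TI against 0 and 1, and likelihood-ratio tests of a
linear day effect in mixed-effects models of each block-level measure.

Blocks whose Type-II AUC is undefined (no incorrect trials — not rare at
75% accuracy with 20 trials) carry NaN and are dropped listwise from trend
models rather than imputed at chance, which would bias training slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import roc
from .observer import ExperimentConfig
from .protocol import PREPOST_BLOCKS
from .quest import gaussian_prior, threshold_from_trials

__all__ = [
    "TransferResult",
    "block_metrics",
    "prepost_thresholds",
    "transfer_index",
    "pooled_daily_auc",
    "trend_test",
    "cohort_stats",
]

BLOCK_MEASURES = [
    "threshold", "type1_auc", "type2_auc",
    "conf_mean_correct", "conf_mean_incorrect",
    "conf_var_correct", "conf_var_incorrect",
]


@dataclass(frozen=True)
class TransferResult:
    """Percent threshold improvements and the transfer index."""

    improvement_trained: float
    improvement_untrained: float
    ti: float


def _quest_kwargs(config: ExperimentConfig) -> dict:
    return dict(
        spec=config.spec,
        grid=config.grid,
        prior=gaussian_prior(config.grid, config.prior_center, config.prior_sd),
        target_p=config.target_p,
    )


def block_metrics(trials: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    """Per-(day, block, condition) measures from the training phase.

    Thresholds are posterior modes rebuilt from each block's own 20 trials
    (offline re-estimation, distinct from the trailing-80 online updates).
    Raises if a block contains more than one intensity for one condition,
    which would violate the fixed-intensity design.
    """
    tr = trials[trials["phase"] == "training"]
    if tr.empty:
        raise ValueError("no training-phase trials in table")
    qk = _quest_kwargs(config)
    out = []
    for (subject, day, block, cond), g in tr.groupby(
        ["subject", "day", "block", "condition"], sort=True
    ):
        intensities = g["intensity"].unique()
        if len(intensities) != 1:
            raise ValueError(
                f"block {day}/{block} condition {cond} has multiple intensities: "
                f"{intensities}"
            )
        if len(g) < config.trials_per_block:
            warnings.warn(
                f"block {day}/{block} condition {cond} has only {len(g)} trials"
            )
        summ = roc.confidence_summary(g)
        out.append({
            "subject": subject, "day": day, "block": block, "condition": cond,
            "condition_role": g["condition_role"].iloc[0],
            "intensity": float(intensities[0]),
            "threshold": threshold_from_trials(
                zip(g["intensity"], g["correct"]), **qk
            ),
            "type1_auc": roc.type1_auc_from_arrays(
                (g["true_alt"] == "A").to_numpy(),
                (g["response"] == "A").to_numpy(),
                g["confidence"].to_numpy(),
            ),
            "type2_auc": roc.type2_auc_from_arrays(
                g["correct"].to_numpy(), g["confidence"].to_numpy()
            ),
            "conf_mean_correct": summ.mean_correct,
            "conf_mean_incorrect": summ.mean_incorrect,
            "conf_var_correct": summ.var_correct,
            "conf_var_incorrect": summ.var_incorrect,
            "n_correct": summ.n_correct,
            "n_incorrect": summ.n_incorrect,
        })
    return pd.DataFrame(out)


def prepost_thresholds(trials: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    """Staircase thresholds per condition set and phase.

    Each pre/post block contributes one 40-trial staircase per condition;
    its posterior mode is the staircase threshold.  Thresholds are averaged
    over a condition's staircases, then over the set's two conditions,
    yielding one row per (subject, set role, phase).
    """
    qk = _quest_kwargs(config)
    per_staircase = []
    for phase in ("pre", "post"):
        ph = trials[trials["phase"] == phase]
        if ph.empty:
            raise ValueError(f"no {phase}-training trials in table")
        for (subject, block, cond), g in ph.groupby(["subject", "block", "condition"]):
            per_staircase.append({
                "subject": subject, "phase": phase, "block": block,
                "condition": cond, "condition_role": g["condition_role"].iloc[0],
                "threshold": threshold_from_trials(
                    zip(g["intensity"], g["correct"]), **qk
                ),
            })
        expected = PREPOST_BLOCKS * (len(config.trained) + len(config.untrained))
        found = len([r for r in per_staircase if r["phase"] == phase])
        if found % expected:
            raise ValueError(
                f"{phase}: expected a multiple of {expected} staircases, found {found}"
            )
    df = pd.DataFrame(per_staircase)
    return (
        df.groupby(["subject", "condition_role", "phase"], as_index=False)["threshold"]
        .mean()
    )


def transfer_index(prepost: pd.DataFrame) -> pd.DataFrame:
    """Transfer index per subject from set-level pre/post thresholds.

    Improvement = (pre - post) / pre * 100 (percent); TI = untrained
    improvement / trained improvement, NaN when the trained improvement is
    zero.
    """
    wide = prepost.pivot_table(
        index="subject", columns=["condition_role", "phase"], values="threshold"
    )
    out = []
    for subject, row in wide.iterrows():
        imp = {}
        for role in ("trained", "untrained"):
            pre, post = row[(role, "pre")], row[(role, "post")]
            if pre <= 0:
                raise ValueError(f"{subject}: non-positive pre-training threshold")
            imp[role] = (pre - post) / pre * 100.0
        ti = imp["untrained"] / imp["trained"] if imp["trained"] != 0 else np.nan
        out.append({
            "subject": subject,
            "improvement_trained": imp["trained"],
            "improvement_untrained": imp["untrained"],
            "ti": ti,
        })
    return pd.DataFrame(out)


def pooled_daily_auc(trials: pd.DataFrame) -> pd.DataFrame:
    """Daily Type-I/II AUC pooling each day's training trials (480/day in the
    reference design) across blocks and trained conditions."""
    tr = trials[trials["phase"] == "training"]
    if tr.empty:
        raise ValueError("no training-phase trials in table")
    out = []
    for (subject, day), g in tr.groupby(["subject", "day"]):
        out.append({
            "subject": subject, "day": day, "n_trials": len(g),
            "type1_auc": roc.type1_auc_from_arrays(
                (g["true_alt"] == "A").to_numpy(),
                (g["response"] == "A").to_numpy(),
                g["confidence"].to_numpy(),
            ),
            "type2_auc": roc.type2_auc_from_arrays(
                g["correct"].to_numpy(), g["confidence"].to_numpy()
            ),
        })
    return pd.DataFrame(out)


def trend_test(metrics: pd.DataFrame, measure: str) -> dict:
    """Likelihood-ratio test for a linear day effect on a block-level measure.

    Fits mixed-effects models (ML) with a by-subject random intercept and
    slope for day, with and without the fixed day effect, and compares them
    with a chi-squared(1) likelihood-ratio test.  If the random-slope fit
    fails or is singular, falls back to a random-intercept model (reported
    in the result).  Rows with missing values are dropped listwise.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    d = metrics[["subject", "day", measure]].dropna().copy()
    if d["subject"].nunique() < 2:
        raise ValueError("trend_test needs >= 2 subjects")
    d = d.rename(columns={measure: "value"})
    d["day_c"] = d["day"] - d["day"].mean()

    def _fit(re_formula):
        # Powell is the most reliable optimizer for these variance surfaces;
        # gradient-based methods frequently stall far from the optimum.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            full = smf.mixedlm(
                "value ~ day_c", d, groups=d["subject"], re_formula=re_formula
            ).fit(reml=False, method="powell")
            reduced = smf.mixedlm(
                "value ~ 1", d, groups=d["subject"], re_formula=re_formula
            ).fit(reml=False, method="powell")
        return full, reduced

    fallback = False
    try:
        full, reduced = _fit("~day_c")
        ok = full.converged and reduced.converged
        if not ok or not np.isfinite(full.llf - reduced.llf):
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, ValueError):
        fallback = True
        full, reduced = _fit(None)

    lrt = max(2.0 * (full.llf - reduced.llf), 0.0)
    return {
        "measure": measure,
        "chi2": float(lrt),
        "p": float(stats.chi2.sf(lrt, df=1)),
        "slope": float(full.params["day_c"]),
        "n": int(len(d)),
        "n_dropped": int(len(metrics) - len(d)),
        "random_slope": not fallback,
    }


def cohort_stats(
    metrics: pd.DataFrame,
    prepost: pd.DataFrame,
    transfer: pd.DataFrame,
    measures: list[str] | None = None,
) -> dict:
    """Cohort-level statistical report.

    Parameters are the concatenated outputs of :func:`block_metrics`,
    :func:`prepost_thresholds` and :func:`transfer_index` over subjects.
    ``measures`` restricts which block measures get trend tests (default:
    all of :data:`BLOCK_MEASURES`).
    """
    if metrics["subject"].nunique() < 2:
        raise ValueError("cohort_stats needs >= 2 subjects")
    report: dict = {"n_subjects": int(metrics["subject"].nunique())}

    wide = prepost.pivot_table(
        index="subject", columns=["condition_role", "phase"], values="threshold"
    )
    report["prepost_wilcoxon"] = {}
    for role in ("trained", "untrained"):
        res = stats.wilcoxon(
            wide[(role, "pre")], wide[(role, "post")], alternative="greater"
        )
        report["prepost_wilcoxon"][role] = {
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "median_pre": float(wide[(role, "pre")].median()),
            "median_post": float(wide[(role, "post")].median()),
        }

    ti = transfer["ti"].dropna()
    t0 = stats.ttest_1samp(ti, 0.0, alternative="greater")
    t1 = stats.ttest_1samp(ti, 1.0, alternative="less")
    report["transfer"] = {
        "mean_ti": float(ti.mean()),
        "sd_ti": float(ti.std(ddof=1)),
        "n": int(len(ti)),
        "p_greater_than_0": float(t0.pvalue),
        "p_less_than_1": float(t1.pvalue),
    }

    report["trends"] = {}
    for measure in measures if measures is not None else BLOCK_MEASURES:
        report["trends"][measure] = trend_test(metrics, measure)
    return report
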