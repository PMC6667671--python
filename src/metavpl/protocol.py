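"""The 3-day staircase-clamped training schedule.

Day 1 starts with pre-training: two blocks, each containing one 40-trial
trial-to-trial QUEST staircase per condition (trained and untrained,
randomly interleaved, independent priors).  Then come 12 training blocks of
20 trials per trained condition in which the intensity is *fixed* within the
block and recomputed between blocks from the trailing ``window`` (80) trials
of that condition — so block 1 uses the condition's last 80 pre-training
trials, block 2 the last 60 pre-training plus the 20 block-1 trials, and so
on.  Days 2 and 3 begin with two 80-trial baseline blocks (40 trial-to-trial
trials per trained condition, posterior seeded from the trailing window)
followed by their 12 training blocks; day 3 ends with post-training, a
mirror of pre-training.

The point of the block-to-block mode is to clamp objective accuracy near the
staircase target (75%) while still providing, within every block, a run of
trials at one fixed intensity from which bias-free Type-I and Type-II ROC
metrics can be computed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .quest import gaussian_prior, init, recommend, threshold_from_trials, update

__all__ = ["run_blockwise_protocol", "TRIAL_COLUMNS", "PREPOST_BLOCKS"]

TRIAL_COLUMNS = [
    "subject", "day", "phase", "block", "condition", "condition_role",
    "intensity", "true_alt", "response", "correct", "confidence",
]

PREPOST_BLOCKS = 2  # pre- and post-training each comprise 2 staircase blocks


def _prior(config) -> np.ndarray:
    return gaussian_prior(config.grid, config.prior_center, config.prior_sd)


def _seeded_state(config, window):
    """Staircase state whose posterior already reflects a trial window."""
    state = init(config.grid, _prior(config), config.spec, config.target_p, config.rule)
    if not window:
        return state
    x = np.array([w[0] for w in window], dtype=float)
    c = np.array([bool(w[1]) for w in window])
    p = config.spec.p_correct(x[:, None], state.grid[None, :], config.target_p)
    like = np.where(c[:, None], p, 1.0 - p)
    logpost = np.log(state.prior) + np.log(np.clip(like, 1e-300, None)).sum(axis=0)
    post = np.exp(logpost - logpost.max())
    return init(config.grid, post / post.sum(), config.spec, config.target_p, config.rule)


def _window(history: list, n: int, context: str) -> list:
    if len(history) < n:
        warnings.warn(
            f"{context}: only {len(history)} trials available for a {n}-trial "
            "window; using all of them",
            stacklevel=3,
        )
    return history[-n:]


def run_blockwise_protocol(
    observer, config, seed: int = 0, subject: str = "s01"
) -> pd.DataFrame:
    """Run one subject through the full schedule; returns the trial table.

    ``observer`` must expose ``reset(seed)``, ``respond(condition,
    intensity, t, trained)`` and ``respond_block(condition, intensity, t,
    trained, n)`` (see :mod:`metavpl.observer`).  ``t`` passed to the
    observer counts completed training blocks, the learning clock.
    """
    ss = np.random.SeedSequence(seed)
    obs_seed, order_seed = ss.spawn(2)
    observer.reset(obs_seed)
    order_rng = np.random.default_rng(order_seed)

    all_conds = list(config.trained) + list(config.untrained)
    role = {c: ("trained" if c in config.trained else "untrained") for c in all_conds}
    history: dict[str, list] = {c: [] for c in all_conds}
    rows: list[dict] = []
    bpd = config.training_blocks_per_day

    def record(day, phase, block, cond, x, ta, ra, co, cf):
        rows.append({
            "subject": subject, "day": day, "phase": phase, "block": block,
            "condition": cond, "condition_role": role[cond], "intensity": x,
            "true_alt": ta, "response": ra, "correct": co, "confidence": cf,
        })

    def staircase_phase(day: int, phase: str, t: float) -> None:
        # PREPOST_BLOCKS blocks x one fresh 40-trial staircase per condition.
        for block in range(1, PREPOST_BLOCKS + 1):
            stairs = {
                c: init(config.grid, _prior(config), config.spec,
                        config.target_p, config.rule)
                for c in all_conds
            }
            sequence = order_rng.permutation(
                np.repeat(all_conds, config.staircase_trials)
            )
            for cond in sequence:
                x = recommend(stairs[cond])
                ta, ra, co, cf = observer.respond(cond, x, t, role[cond] == "trained")
                stairs[cond] = update(stairs[cond], x, co)
                history[cond].append((x, co))
                record(day, phase, block, cond, x, ta, ra, co, cf)

    def baseline_phase(day: int) -> None:
        t = (day - 1) * bpd
        for block in range(1, config.baseline_blocks + 1):
            stairs = {
                c: _seeded_state(
                    config, _window(history[c], config.window, f"baseline day {day}")
                )
                for c in config.trained
            }
            sequence = order_rng.permutation(
                np.repeat(list(config.trained), config.baseline_trials)
            )
            for cond in sequence:
                x = recommend(stairs[cond])
                ta, ra, co, cf = observer.respond(cond, x, t, True)
                stairs[cond] = update(stairs[cond], x, co)
                history[cond].append((x, co))
                record(day, "baseline", block, cond, x, ta, ra, co, cf)

    def training_phase(day: int) -> None:
        for block in range(1, bpd + 1):
            t = (day - 1) * bpd + (block - 1)
            block_rows_start = len(rows)
            for cond in config.trained:
                window = _window(
                    history[cond], config.window, f"training day {day} block {block}"
                )
                thr = threshold_from_trials(
                    window, config.spec, config.grid, _prior(config), config.target_p
                )
                x = config.rule.quantize(thr)
                ta, ra, co, cf = observer.respond_block(
                    cond, x, t, True, config.trials_per_block
                )
                for i in range(config.trials_per_block):
                    record(day, "training", block, cond, x,
                           "A" if ta[i] else "B", "A" if ra[i] else "B",
                           bool(co[i]), int(cf[i]))
                history[cond].extend(
                    (x, bool(co[i])) for i in range(config.trials_per_block)
                )
            # random interleaving of the trained conditions within the block
            block_rows = rows[block_rows_start:]
            perm = order_rng.permutation(len(block_rows))
            rows[block_rows_start:] = [block_rows[i] for i in perm]

    for day in range(1, config.days + 1):
        if day == 1:
            staircase_phase(day, "pre", t=0.0)
        else:
            baseline_phase(day)
        training_phase(day)
    staircase_phase(config.days, "post", t=float(config.days * bpd))

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["correct"] = df["correct"].astype(bool)
    df["confidence"] = df["confidence"].astype(int)
    return df
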