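"""Reading and writing the shared trial-table CSV schema."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .protocol import TRIAL_COLUMNS

__all__ = ["write_trials", "read_trials", "write_manifest", "read_manifest"]

_DTYPES = {
    "subject": str,
    "day": int,
    "phase": str,
    "block": int,
    "condition": str,
    "condition_role": str,
    "intensity": float,
    "true_alt": str,
    "response": str,
    "correct": bool,
    "confidence": int,
}


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (losslessly round-trippable)."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks columns {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table CSV with the canonical dtypes."""
    df = pd.read_csv(path, dtype={k: v for k, v in _DTYPES.items() if v is not bool})
    df["correct"] = df["correct"].astype(bool)
    return df[TRIAL_COLUMNS]


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
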