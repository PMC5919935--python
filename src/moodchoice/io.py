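"""Trial-table and report serialization.

Trial tables travel as CSV with a fixed column order (see
``synthetic.TRIAL_COLUMNS``); missing values are written as empty fields.
A cohort is one CSV per agent plus a JSON manifest holding seeds and
ground-truth parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .choice import ChoiceModelSpec, ChoiceParams
from .mood import MoodModelSpec, MoodParams
from .synthetic import TRIAL_COLUMNS, AgentGroundTruth

__all__ = [
    "read_trials",
    "write_trials",
    "write_cohort",
    "read_cohort",
    "to_jsonable",
]

REQUIRED_COLUMNS = [
    "session", "trial", "difficulty", "accuracy_mean", "correct", "feedback",
    "gain", "loss", "size", "choice",
]
OPTIONAL_COLUMNS = [c for c in TRIAL_COLUMNS if c not in REQUIRED_COLUMNS]

_FLOAT_COLS = ["accuracy_mean", "gain", "loss", "size", "choice",
               "mood_rating", "confidence_rating", "vmpfc", "ains", "global"]
_INT_COLS = ["session", "trial", "correct", "feedback"]


def write_trials(table: pd.DataFrame, path) -> None:
    """Write one agent's trial table as CSV (fixed column order)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table lacks required columns: {missing}")
    cols = [c for c in TRIAL_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False, na_rep="")


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table CSV, validating schema and row integrity."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in _INT_COLS:
        bad = df[c].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed row at line {line}: "
                             f"missing {c!r}")
        df[c] = df[c].astype(int)
    for c in _FLOAT_COLS:
        if c in df.columns:
            df[c] = df[c].astype(float)
    if not (np.diff(df["trial"].to_numpy()) > 0).all():
        raise ValueError(f"{path}: trial index must be strictly increasing")
    if ((df["correct"] == 1) & (df["feedback"] == -1)).any():
        raise ValueError(f"{path}: correct trials cannot carry negative "
                         "feedback")
    return df


def to_jsonable(obj):
    """Recursively convert package objects to JSON-serializable values."""
    if isinstance(obj, (MoodParams, ChoiceParams)):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_cohort(tables, truths, out_dir, seed: int | None = None) -> None:
    """One CSV per agent plus a JSON manifest with seeds and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"n_agents": len(tables), "seed": seed, "agents": []}
    for i, (table, truth) in enumerate(zip(tables, truths)):
        fname = f"agent_{i:03d}.csv"
        write_trials(table, out / fname)
        manifest["agents"].append({
            "file": fname,
            "ground_truth": to_jsonable(truth),
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(in_dir):
    """Load trial tables (and the manifest, if present) from a directory."""
    d = Path(in_dir)
    manifest_path = d / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        tables = [read_trials(d / a["file"]) for a in manifest["agents"]]
    else:
        manifest = None
        tables = [read_trials(p) for p in sorted(d.glob("agent_*.csv"))]
    return tables, manifest
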