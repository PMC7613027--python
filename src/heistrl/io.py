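"""Schema-validated reading and writing of pipeline tables.

TrialTables and trajectories travel as CSV, voxel patterns as TSV with an
aligned metadata CSV, and fits as JSON.  Validation errors name the offending
column or row counts so that malformed inputs fail loudly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .hierfit import GroupPrior, SubjectFit
from .synth_neural import VoxelDataset
from .task import TRIAL_COLUMNS

ENUMS = {
    "condition": {"dependent", "independent"},
    "trial_type": {"forced", "free"},
    "valence": {"gain", "loss"},
    "door_presented": {"dark", "light"},
    "choice": {"dark", "light", "missed"},
    "state": {"heist", "neutral"},
}


class ValidationError(ValueError):
    pass


def validate_trial_table(df: pd.DataFrame, require_choices: bool = False) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"TrialTable missing columns: {missing}")
    for col, allowed in ENUMS.items():
        vals = set(df[col].dropna().unique())
        bad = vals - allowed
        if bad:
            raise ValidationError(f"column {col!r} has invalid values {sorted(bad)}")
    if require_choices and df["choice"].isna().any():
        raise ValidationError("TrialTable has unfilled choices")
    if df["p_true"].isna().any() or ((df["p_true"] < 0) | (df["p_true"] > 1)).any():
        raise ValidationError("p_true must be probabilities")
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    validate_trial_table(df)
    df.to_csv(path, index=False)


def read_trial_table(path, require_choices: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("choice", "state"):
        if col in df.columns:
            df[col] = df[col].where(df[col].notna(), pd.NA)
    return validate_trial_table(df, require_choices=require_choices)


def write_voxel_dataset(dataset: VoxelDataset, pattern_path, metadata_path) -> None:
    pd.DataFrame(dataset.patterns).to_csv(pattern_path, sep="\t", index=False, header=False)
    dataset.metadata.to_csv(metadata_path, index=False)


def read_voxel_dataset(pattern_path, metadata_path) -> VoxelDataset:
    patterns = pd.read_csv(pattern_path, sep="\t", header=None).to_numpy(dtype=float)
    metadata = pd.read_csv(metadata_path)
    if len(patterns) != len(metadata):
        raise ValidationError(
            f"pattern rows ({len(patterns)}) != metadata rows ({len(metadata)})"
        )
    return VoxelDataset(patterns=patterns, metadata=metadata)


def write_fits(path, prior: GroupPrior, fits: Sequence[SubjectFit],
               loocv: Optional[np.ndarray] = None) -> None:
    payload = {
        "group_prior": {"mean": prior.mean.tolist(), "var": prior.var.tolist()},
        "subjects": [
            {
                "params": asdict(f.map_params_natural),
                "params_transformed": f.map_params_transformed.tolist(),
                "log_marginal": f.log_marginal,
                "converged": f.converged,
                "loocv_score": None if loocv is None else float(loocv[i]),
            }
            for i, f in enumerate(fits)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fits(path) -> Dict:
    return json.loads(Path(path).read_text())


#: default mapping from the deposited behavioural files' column names onto
#: TrialTable columns (a thin adapter; override per file layout)
DEPOSITED_COLUMN_MAP = {
    "subject": "subject",
    "session": "session",
    "block": "block",
    "condition": "condition",
    "context": "context",
    "trial": "trial_index",
    "trial_type": "trial_type",
    "valence": "valence",
    "door_presented": "door_presented",
    "choice": "choice",
    "state": "state",
    "outcome": "outcome",
    "p_true": "p_true",
}


def ingest_deposited_choices(
    path, column_map: Optional[Dict[str, str]] = None, drop_missed: bool = True
) -> pd.DataFrame:
    """Map an externally deposited behavioural CSV onto a valid TrialTable.

    ``column_map`` maps source column names to TrialTable names; enum values
    are lower-cased.  Missed trials are dropped by default, matching the
    original exclusion rule.
    """
    cmap = dict(DEPOSITED_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    missing = [src for src in cmap if src not in raw.columns]
    if missing:
        raise ValidationError(f"deposited file lacks expected columns: {missing}")
    df = raw[list(cmap)].rename(columns=cmap)
    for col in ENUMS:
        df[col] = df[col].astype(str).str.lower().replace({"nan": pd.NA, "<na>": pd.NA})
    if drop_missed:
        df = df[df["choice"] != "missed"].reset_index(drop=True)
    df = df[TRIAL_COLUMNS]
    return validate_trial_table(df)
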