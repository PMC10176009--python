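"""CSV trial logs and JSON sidecars.

Trial logs are small (hundreds of rows) and human-auditable, so they
are stored as plain CSV with a documented header; stimulus/gamble
definitions, seeds and parameters travel in JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import task_design as td
from .errors import DataError
from .model_core import PeirsParams

__all__ = [
    "EXPERIENCE_COLUMNS",
    "DESCRIPTION_COLUMNS",
    "write_trials",
    "read_trials",
    "write_json",
    "read_json",
    "params_to_dict",
    "params_from_dict",
    "file_sha256",
]

EXPERIENCE_COLUMNS = ("trial", "block", "stim_set", "trial_type",
                      "option_left", "option_right")
DESCRIPTION_COLUMNS = ("trial", "block", "gamble_id")


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
    return path


def read_trials(path: str | Path, task: str = "experience") -> pd.DataFrame:
    """Load a trial log, validating the required header for the task.

    Unknown extra columns are preserved; a missing required column
    raises a DataError naming it.
    """
    required = EXPERIENCE_COLUMNS if task == "experience" else DESCRIPTION_COLUMNS
    df = pd.read_csv(path, keep_default_na=False,
                     na_values=[""], dtype={"option_right": str}
                     if task == "experience" else None)
    for col in required:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column '{col}'")
    if task == "experience" and "option_right" in df.columns:
        df["option_right"] = df["option_right"].fillna("").astype(str)
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def params_to_dict(p: PeirsParams) -> Dict[str, float]:
    return dataclasses.asdict(p)


def params_from_dict(d: Dict[str, float]) -> PeirsParams:
    return PeirsParams(**d)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def stimulus_sets_to_json(sets) -> List[List[Dict]]:
    return [[dataclasses.asdict(s) for s in one] for one in sets]


def gambles_to_json(gambles: Sequence[td.GambleSpec]) -> List[Dict]:
    return [dataclasses.asdict(g) for g in gambles]
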