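"""Delimited-text data exchange and run manifests.

All tabular data moves through plain CSV with documented headers.  Trial
tables use one row per offer; the ``success`` field is empty for refused
offers and for accepted offers whose exertion phase was omitted.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .synthetic_cohort import CohortData

__all__ = ["IOError_", "TRIAL_COLUMNS", "read_trials", "write_trials",
           "read_participants", "write_participants", "RunManifest"]


class IOError_(ValueError):
    """Malformed or inconsistent data file."""


TRIAL_COLUMNS = ("participant_id", "group", "age", "trial_index",
                 "reward_apples", "effort_prop", "accepted",
                 "exertion_omitted", "success")


def _line(i: int) -> int:
    # data row i sits on file line i+2 (header is line 1)
    return i + 2


def _validate_trials(df: pd.DataFrame, path: str = "<memory>") -> None:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise IOError_(f"{path}: missing columns {sorted(missing)}")
    for col in ("reward_apples", "effort_prop", "trial_index", "accepted",
                "exertion_omitted"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise IOError_(f"{path}: line {_line(bad[0])}: "
                           f"non-numeric value in column {col!r}")
    bad = df.index[(df["effort_prop"] <= 0) | (df["effort_prop"] > 1)]
    if len(bad):
        raise IOError_(f"{path}: line {_line(bad[0])}: "
                       f"effort_prop {df.loc[bad[0], 'effort_prop']} outside (0, 1]")
    bad = df.index[df["reward_apples"] <= 0]
    if len(bad):
        raise IOError_(f"{path}: line {_line(bad[0])}: non-positive reward")
    bad = df.index[~df["accepted"].isin([0, 1])]
    if len(bad):
        raise IOError_(f"{path}: line {_line(bad[0])}: accepted must be 0/1")
    # success only defined on accepted, non-omitted trials
    no_outcome = (df["accepted"] == 0) | (df["exertion_omitted"] == 1)
    bad = df.index[no_outcome & df["success"].notna()]
    if len(bad):
        raise IOError_(f"{path}: line {_line(bad[0])}: success recorded on a "
                       "refused or exertion-omitted trial")
    # schedule consistency: identical cell multiset for every subject
    counts = df.groupby(["participant_id", "reward_apples", "effort_prop"]) \
               .size().unstack(["reward_apples", "effort_prop"]).fillna(-1)
    if len(counts) > 1:
        # majority pattern is the reference, so the deviant subject is named
        patterns = counts.apply(tuple, axis=1)
        ref = patterns.mode().iloc[0]
        mism = patterns.index[patterns != ref]
        if len(mism):
            raise IOError_(f"{path}: inconsistent schedule for subject "
                           f"{mism[0]!r}")


def read_trials(path) -> CohortData:
    """Read a trial-level CSV into a CohortData (participants derived)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise IOError_(f"{path}: {exc}") from exc
    _validate_trials(df, str(path))
    participants = (df.drop_duplicates("participant_id")
                    [["participant_id", "group", "age"]].reset_index(drop=True))
    return CohortData(participants=participants, trials=df)


def write_trials(cohort: CohortData, path) -> Path:
    """Write the trial table as CSV (empty success field where undefined)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in TRIAL_COLUMNS if c in cohort.trials.columns]
    extra = [c for c in cohort.trials.columns if c not in cols]
    cohort.trials[cols + extra].to_csv(path, index=False)
    return path


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise IOError_(f"{path}: missing participant_id column")
    return df


def write_participants(participants: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    participants.to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    stage: str
    seed: Optional[int]
    config_hash: Optional[str] = None
    settings: Dict = field(default_factory=dict)
    files: Dict[str, str] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def add_file(self, path) -> None:
        p = Path(path)
        self.files[p.name] = _sha256(p)

    def write(self, path) -> Path:
        from . import __version__

        self.version = self.version or __version__
        self.timestamp = self.timestamp or time.strftime(
            "%Y-%m-%dT%H:%M:%S", time.gmtime())
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
        return path
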