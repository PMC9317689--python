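"""Delimited-text readers/writers for trial data, BLUEs and matrices.

Every file written carries a leading ``#`` comment with the tool version,
seed and config hash of the run that produced it; readers skip comments.
All tables are comma-delimited UTF-8 with a header row; matrices carry
trait-name row and column labels.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .simulate import KEY_COLUMNS, TrialData

__all__ = [
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
    "write_trial",
    "read_trial",
]


def _header(seed=None, config_hash=None) -> str:
    parts = [f"selindex {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return "# " + " ".join(parts) + "\n"


def write_table(df: pd.DataFrame, path, seed=None, config_hash=None,
                index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, config_hash))
        df.to_csv(fh, index=index)
    return path


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def write_matrix(M: pd.DataFrame, path, seed=None, config_hash=None) -> Path:
    return write_table(M, path, seed=seed, config_hash=config_hash, index=True)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def write_trial(trial: TrialData, path, truth_path=None, seed=None,
                config_hash=None) -> Path:
    out = write_table(trial.data, path, seed=seed, config_hash=config_hash)
    if truth_path is not None and trial.truth is not None:
        write_table(trial.truth, truth_path, seed=seed, config_hash=config_hash,
                    index=True)
    return out


def read_trial(path, truth_path=None) -> TrialData:
    data = read_table(path)
    traits = tuple(c for c in data.columns if c not in KEY_COLUMNS)
    truth = None
    if truth_path is not None and Path(truth_path).exists():
        truth = read_table(truth_path, index_col=0)
    return TrialData(data=data, trait_names=traits, truth=truth)
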