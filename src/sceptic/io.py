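"""Delimited-table IO for trial logs, truth tables and latent trajectories.

All on-disk formats are plain text: tab-separated tables with a documented
header and flat YAML key/value configs (see ``BasisConfig.to_file``).
Writers are deterministic so fixed-seed pipelines are byte-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["write_table", "read_table", "write_trajectories",
           "read_trajectories"]

_FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path) -> None:
    """Write a delimited (TSV) table with stable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trajectories(traj: np.ndarray, path, subject=0, run=0,
                       kind: str = "element") -> None:
    """Write a (n_trials, n) weight or value trajectory in long format
    (subject, run, trial, index, value); ``kind`` names the index column
    ('element' for basis weights, 'bin' for value functions)."""
    n_trials, n = traj.shape
    df = pd.DataFrame({
        "subject": np.repeat(subject, n_trials * n),
        "run": np.repeat(run, n_trials * n),
        "trial": np.repeat(np.arange(n_trials), n),
        kind: np.tile(np.arange(n), n_trials),
        "value": np.asarray(traj, dtype=float).ravel(),
    })
    write_table(df, path)


def read_trajectories(path, kind: str = "element") -> np.ndarray:
    df = read_table(path)
    n_trials = df["trial"].nunique()
    n = df[kind].nunique()
    return df.sort_values(["trial", kind])["value"].to_numpy().reshape(n_trials, n)
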