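"""File interchange: events tables (TSV, "NA" for missing), trace matrices
(.npy with a JSON sidecar), and generic result tables (TSV, 6 significant
digits)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.6g"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    write_table(events, path)


def read_events(path: str | Path) -> pd.DataFrame:
    return read_table(path)


def write_traces(traces: np.ndarray, sidecar: dict, path_prefix: str | Path) -> None:
    """Write a (trials x samples) matrix to ``<prefix>.npy`` and its metadata
    to ``<prefix>.json``."""
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), traces)
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_traces(path_prefix: str | Path) -> tuple[np.ndarray, dict]:
    prefix = Path(path_prefix)
    traces = np.load(prefix.with_suffix(".npy"))
    with open(prefix.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return traces, sidecar
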