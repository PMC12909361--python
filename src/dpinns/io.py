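"""Readers/writers for aggregated series, estimate reports and run logs."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AggregatedSeries, CohortData

__all__ = ["read_aggregated_csv", "write_aggregated_csv",
           "write_cohort_csv", "write_json", "RunLog"]


def read_aggregated_csv(path, dialect: str = "auto") -> AggregatedSeries:
    """Read a `time,mean,sd|var[,n]` CSV into an AggregatedSeries.

    `dialect` is 'sd', 'var' or 'auto' (pick whichever column is present);
    SD is converted to variance internally."""
    df = pd.read_csv(path)
    if "time" not in df or "mean" not in df:
        raise ValueError(f"{path}: need 'time' and 'mean' columns")
    if dialect == "auto":
        dialect = "var" if "var" in df else "sd"
    if dialect not in df:
        raise ValueError(f"{path}: missing '{dialect}' column")
    t = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    spread = df[dialect].to_numpy(dtype=float)
    bad = np.where(spread < 0)[0]
    if bad.size:
        raise ValueError(f"{path}: negative {dialect} in row {bad[0]}")
    var = spread ** 2 if dialect == "sd" else spread
    n = df["n"].to_numpy(dtype=int) if "n" in df else None
    return AggregatedSeries(t, df["mean"].to_numpy(dtype=float), var, n)


def write_aggregated_csv(series: AggregatedSeries, path,
                         dialect: str = "var") -> None:
    series.to_frame(dialect=dialect).to_csv(path, index=False)


def write_cohort_csv(cohort: CohortData, path) -> None:
    """Individual-level long-format export (subject, time, true, observed,
    observed-flag) for inspection."""
    n_sub, n_t = cohort.profiles_observed.shape
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n_sub), n_t),
        "time": np.tile(cohort.times, n_sub),
        "true": cohort.profiles_true.ravel(),
        "observed": cohort.profiles_observed.ravel(),
        "included": cohort.mask.ravel(),
    })
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")


class RunLog:
    """Timestamped event log; every stochastic component's seed is recorded
    so any artifact is regenerable from config + seed."""

    def __init__(self):
        self.events = []

    def log(self, event: str, **info):
        self.events.append({"t": time.strftime("%Y-%m-%dT%H:%M:%S"),
                            "event": event, **info})

    def write(self, path):
        write_json(self.events, path)
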