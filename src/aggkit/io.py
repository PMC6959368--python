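"""Plate-reader CSV / metadata JSON dialect.

Traces travel as a wide CSV — a ``time`` column plus one signal column per
well — with a companion JSON file mapping each well id to its experimental
context::

    {"c1r1": {"m0_uM": 1.0, "replicate": "r1",
              "modality": "tht", "direction": "rising"}, ...}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .traces import AggregationTrace

__all__ = ["read_traces_csv", "write_traces_csv", "group_by_concentration"]


def write_traces_csv(
    traces: Sequence[AggregationTrace],
    metadata: dict,
    csv_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write traces (shared time grid) and their well metadata."""
    if not traces:
        raise ValueError("no traces to write")
    df = pd.DataFrame({"time": traces[0].time})
    for tr in traces:
        if tr.time.shape != traces[0].time.shape or \
                not (tr.time == traces[0].time).all():
            raise ValueError("write_traces_csv requires a shared time grid")
        df[tr.replicate_id] = tr.signal
    df.to_csv(csv_path, index=False)
    Path(meta_path).write_text(json.dumps(metadata, indent=2))


def read_traces_csv(
    csv_path: str | Path, meta_path: str | Path
) -> list[AggregationTrace]:
    """Read the wide trace CSV and its metadata into AggregationTrace objects."""
    df = pd.read_csv(csv_path)
    if "time" not in df.columns:
        raise ValueError("trace CSV must have a 'time' column")
    meta = json.loads(Path(meta_path).read_text())
    traces = []
    for well, info in meta.items():
        if well not in df.columns:
            raise ValueError(f"well {well!r} in metadata but not in CSV")
        sub = df[["time", well]].dropna()
        traces.append(AggregationTrace(
            time=sub["time"].to_numpy(),
            signal=sub[well].to_numpy(),
            m0=float(info["m0_uM"]),
            replicate_id=well,
            modality=info.get("modality", "tht"),
            direction=info.get("direction", "rising"),
            meta={"replicate": info.get("replicate", well)},
        ))
    return traces


def group_by_concentration(
    traces: Sequence[AggregationTrace],
) -> dict[float, list[AggregationTrace]]:
    """Bucket traces by initial monomer concentration (sorted keys)."""
    groups: dict[float, list[AggregationTrace]] = {}
    for tr in traces:
        groups.setdefault(tr.m0, []).append(tr)
    return dict(sorted(groups.items()))
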