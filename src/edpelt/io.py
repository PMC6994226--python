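"""Readers and writers for series and segmentations.

Series come in as one-column CSV/TSV (optionally with an index/time column
and a header); segmentations go out as CSV (1-based inclusive segment
table), JSON (full metadata, round-trippable) or BED (0-based half-open
intervals, the only 0-based surface of the package).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cost_models import TimeSeries
from .search import Segmentation

__all__ = ["read_series", "write_segmentation", "read_segmentation"]


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown series format {fmt!r}")
    return "\t" if fmt == "tsv" else ","


def read_series(path, fmt: str | None = None) -> TimeSeries:
    """Read an ordered univariate series, preserving row order.

    Accepts a single numeric column, or two columns (index/time plus
    value) in which case the last column is used — unless a header names a
    ``value`` column explicitly.  A header row is auto-detected by being
    non-numeric.  Missing or non-numeric entries raise a parse error
    naming the offending (1-based) data row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, fmt), header=None, dtype=str,
                     skip_blank_lines=True, comment="#", na_filter=False)
    first = df.iloc[0]
    has_header = any(not _is_number(v) for v in first)
    columns = [str(v).strip().lower() for v in first] if has_header else None
    if has_header:
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] == 1:
        col = 0
    else:
        col = df.shape[1] - 1
        if columns and "value" in columns:
            col = columns.index("value")
    raw = df.iloc[:, col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.index[values.isna()]
    if len(bad):
        row = int(bad[0]) + 1  # 1-based data row
        raise ValueError(
            f"{path}: non-numeric or missing value {raw.iloc[bad[0]]!r} at data row {row}"
        )
    return TimeSeries(values.to_numpy(dtype=float))


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_segmentation(seg: Segmentation, path, fmt: str = "csv", name: str = "series") -> None:
    """Write a segmentation as csv, json or bed.

    CSV rows are ``segment_index,start,end,cost`` with 1-based inclusive
    coordinates; BED converts to 0-based half-open ``name start end``;
    JSON stores changepoints, per-segment costs, penalty and total cost
    and can be read back with :func:`read_segmentation`.
    """
    path = Path(path)
    if fmt == "csv":
        rows = [
            {"segment_index": i + 1, "start": a, "end": b, "cost": c}
            for i, ((a, b), c) in enumerate(zip(seg.segments, seg.segment_costs))
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif fmt == "json":
        payload = {
            "n": seg.n,
            "m": seg.m,
            "penalty": seg.penalty,
            "total_cost": seg.total_cost,
            "changepoints": list(seg.tau),
            "segment_costs": list(seg.segment_costs),
        }
        path.write_text(json.dumps(payload, indent=2))
    elif fmt == "bed":
        lines = [f"{name}\t{a - 1}\t{b}" for a, b in seg.segments]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown segmentation format {fmt!r}")


def read_segmentation(path) -> Segmentation:
    """Read back a JSON segmentation written by :func:`write_segmentation`."""
    payload = json.loads(Path(path).read_text())
    return Segmentation(
        tau=tuple(payload["changepoints"]),
        n=int(payload["n"]),
        total_cost=float(payload["total_cost"]),
        segment_costs=tuple(payload["segment_costs"]),
        penalty=payload["penalty"],
    )
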