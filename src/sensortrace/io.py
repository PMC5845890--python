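"""Delimited-text trace tables, shift tables, and result records.

Trace tables are CSV with an optional block of ``# key: value`` metadata
header lines. Two layouts are accepted:

* long form — columns ``trace_id,time_s,channel,value`` (channel optional),
* wide form — a ``time_s`` column plus one column per trace.

Events live in a companion CSV with columns ``label,time_s``. Times are
seconds everywhere. Round-tripping a collection through write/read is
lossless up to float formatting (full precision ``repr`` is used).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .nmr import TitrationSeries
from .traces import TimeSeriesTrace

logger = logging.getLogger(__name__)

__all__ = [
    "read_trace_table",
    "write_trace_table",
    "read_events",
    "write_events",
    "read_shift_table",
    "write_shift_table",
    "read_metadata",
    "write_result_json",
    "FormatError",
]


class FormatError(ValueError):
    """Malformed input table."""


def _read_csv_with_metadata(path) -> Tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, val = stripped.partition(":")
                meta[key.strip()] = val.strip()
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])),
                     float_precision="round_trip")
    return df, meta


def read_metadata(path) -> dict:
    """Only the ``# key: value`` header block of a table."""
    return _read_csv_with_metadata(path)[1]


def read_trace_table(
    path,
    events_path=None,
) -> List[TimeSeriesTrace]:
    """Read a long- or wide-form trace table into validated traces.

    Malformed rows (non-finite time/value) and duplicate
    (trace_id, time, channel) keys raise :class:`FormatError` with the
    offending rows identified.
    """
    df, meta = _read_csv_with_metadata(path)
    events = read_events(events_path) if events_path else []
    units = meta.get("units", "a.u.")

    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required 'time_s' column")
    if not np.all(np.isfinite(df["time_s"].to_numpy(dtype=float))):
        bad = df.index[~np.isfinite(df["time_s"].astype(float))].tolist()
        raise FormatError(f"{path}: non-finite time_s at rows {bad}")

    traces: List[TimeSeriesTrace] = []
    if "trace_id" in df.columns and "value" in df.columns:  # long form
        key_cols = ["trace_id", "time_s"] + (
            ["channel"] if "channel" in df.columns else []
        )
        dup = df.duplicated(subset=key_cols)
        if dup.any():
            raise FormatError(
                f"{path}: duplicate (trace_id, time, channel) rows at "
                f"{df.index[dup].tolist()}"
            )
        group_cols = ["trace_id"] + (["channel"] if "channel" in df.columns else [])
        for key, grp in df.groupby(group_cols, sort=False):
            tid = key[0] if isinstance(key, tuple) else key
            channel = key[1] if isinstance(key, tuple) and len(key) > 1 else None
            grp = grp.sort_values("time_s")
            name = str(tid) if channel is None else f"{tid}:{channel}"
            traces.append(
                _make_trace(name, grp["time_s"].to_numpy(),
                            grp["value"].to_numpy(), events, path, units)
            )
    else:  # wide form
        t = df["time_s"].to_numpy(dtype=float)
        for col in df.columns:
            if col == "time_s":
                continue
            traces.append(
                _make_trace(str(col), t, df[col].to_numpy(dtype=float),
                            events, path, units)
            )
    if not traces:
        raise FormatError(f"{path}: no traces found")
    return traces


def _make_trace(name, t, values, events, path, units="a.u.") -> TimeSeriesTrace:
    if not np.all(np.isfinite(values)):
        bad = np.nonzero(~np.isfinite(np.asarray(values, dtype=float)))[0].tolist()
        raise FormatError(f"{path}: trace {name!r} has non-finite values at {bad}")
    in_span = [(lbl, w) for lbl, w in events if t.min() <= w <= t.max()]
    try:
        return TimeSeriesTrace(trace_id=name, t=np.asarray(t, dtype=float),
                               values=np.asarray(values, dtype=float),
                               events=in_span, units=units)
    except ValueError as exc:
        raise FormatError(f"{path}: trace {name!r}: {exc}") from exc


def write_trace_table(
    traces: Sequence[TimeSeriesTrace],
    path,
    metadata: Optional[dict] = None,
    wide: bool = True,
) -> None:
    """Write traces as CSV, with metadata as ``# key: value`` header lines.

    Wide form requires all traces to share a time base; otherwise pass
    ``wide=False`` for long form.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(metadata or {})
    meta.setdefault("units", traces[0].units)
    lines = [f"# {key}: {val}\n" for key, val in meta.items()]
    if wide:
        t0 = traces[0].t
        for tr in traces[1:]:
            if tr.t.shape != t0.shape or not np.array_equal(tr.t, t0):
                raise ValueError("wide form requires a shared time base")
        cols = {"time_s": t0}
        cols.update({tr.trace_id: tr.values for tr in traces})
        df = pd.DataFrame(cols)
    else:
        frames = [
            pd.DataFrame({"trace_id": tr.trace_id, "time_s": tr.t,
                          "value": tr.values})
            for tr in traces
        ]
        df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.writelines(lines)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_events(path) -> List[Tuple[str, float]]:
    df, _ = _read_csv_with_metadata(path)
    if not {"label", "time_s"} <= set(df.columns):
        raise FormatError(f"{path}: events file needs 'label' and 'time_s' columns")
    return [(str(r.label), float(r.time_s)) for r in df.itertuples()]


def write_events(events: Sequence[Tuple[str, float]], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(events, columns=["label", "time_s"]).to_csv(path, index=False)


def read_shift_table(path) -> List[TitrationSeries]:
    """Read per-residue titration shifts: columns residue, conc_mM, delta_n
    (optionally delta_h)."""
    df, _ = _read_csv_with_metadata(path)
    required = {"residue", "conc_mM", "delta_n"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: shift table needs columns {sorted(required)}")
    out = []
    for residue, grp in df.groupby("residue", sort=True):
        grp = grp.sort_values("conc_mM")
        out.append(
            TitrationSeries(
                residue=int(residue),
                ligand_conc=grp["conc_mM"].to_numpy(dtype=float),
                shifts=grp["delta_n"].to_numpy(dtype=float),
            )
        )
    return out


def write_shift_table(series: Sequence[TitrationSeries], path,
                      metadata: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame({"residue": s.residue, "conc_mM": s.ligand_conc,
                      "delta_n": s.shifts})
        for s in series
    ]
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        pd.concat(frames, ignore_index=True).to_csv(
            fh, index=False, float_format="%.17g"
        )


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_result_json(result: dict, path, config: Optional[dict] = None,
                      inputs: Optional[Sequence] = None) -> None:
    """Write a result record with version, effective config, and input
    checksums, using stable key order so diffs are meaningful."""
    from . import __version__

    record = {
        "tool": "sensortrace",
        "version": __version__,
        "config": config or {},
        "inputs": {str(p): sha256_of(p) for p in (inputs or [])},
        "result": result,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return str(obj)
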