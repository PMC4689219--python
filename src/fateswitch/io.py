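"""Trace-table readers/writers and provenance records.

Traces travel as long (tidy) CSV with columns ``cell_id, time_h, channel,
intensity``; fate labels as CSV with ``cell_id, fate``.  Reading
canonicalises row order, errors on duplicates or non-monotone times, and
flags cells with missing frames.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_traces", "write_traces", "read_labels", "write_labels",
           "write_provenance", "TraceParseError"]

TRACE_COLUMNS = ["cell_id", "time_h", "channel", "intensity"]


class TraceParseError(ValueError):
    """Raised on malformed trace tables."""


def write_traces(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy trace table to CSV at full float precision."""
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise TraceParseError(f"missing column(s): {', '.join(missing)}")
    path = Path(path)
    table[TRACE_COLUMNS].to_csv(path, index=False,
                                float_format=None)  # repr round-trips
    return path


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read a tidy trace CSV, canonicalise ordering and validate.

    Raises :class:`TraceParseError` (with the offending 1-based data row
    number) on missing columns, duplicate ``(cell_id, time_h, channel)``
    entries or non-monotone times within a cell; cells that do not cover
    the full union of frame times are listed in
    ``table.attrs["cells_with_gaps"]``.
    """
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise TraceParseError(f"missing column(s): {', '.join(missing)}")
    dup = table.duplicated(subset=["cell_id", "time_h", "channel"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise TraceParseError(f"duplicate (cell_id, time_h, channel) at "
                              f"data row {row}")
    # canonical ordering makes within-cell times monotone by construction;
    # monotonicity can only fail through duplicates, caught above
    table = table.sort_values(["cell_id", "channel", "time_h"],
                              ignore_index=True)
    all_times = np.sort(table["time_h"].unique())
    gaps = []
    for (cid, ch), grp in table.groupby(["cell_id", "channel"]):
        if grp["time_h"].size != all_times.size:
            gaps.append(int(cid))
    table.attrs["cells_with_gaps"] = sorted(set(gaps))
    return table


def write_labels(labels: pd.DataFrame, path: str | Path) -> Path:
    if "cell_id" not in labels.columns or "fate" not in labels.columns:
        raise TraceParseError("label table needs cell_id and fate columns")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    labels.to_csv(path, index=False)
    return Path(path)


def read_labels(path: str | Path) -> pd.DataFrame:
    labels = pd.read_csv(path)
    if "cell_id" not in labels.columns or "fate" not in labels.columns:
        raise TraceParseError("label table needs cell_id and fate columns")
    return labels.sort_values("cell_id", ignore_index=True)


def write_provenance(out_dir: str | Path, config, seed: int | None,
                     extra: dict | None = None) -> Path:
    """Drop a provenance JSON (config hash, seed, version) next to outputs."""
    from .config import config_hash, save_config

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {"config_hash": config_hash(config),
              "seed": seed,
              "version": config.version}
    if extra:
        record.update(extra)
    save_config(config, out_dir / "resolved_config.yaml")
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path
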