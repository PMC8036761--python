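"""CSV schemas for raw pulses and slope series.

Raw pulse table: columns ``pulse_index, onset_s, current_A, t_rel_s,
voltage_V`` (header mandatory, UTF-8, '.' decimal separator), rows
sorted by (pulse_index, t_rel_s) and unique, current constant within a
pulse.  Voltages are serialised with 10 significant digits so a
write/read round trip preserves values to the declared precision.

Slope series table: columns ``pulse_index, t_h, slope, intercept, r2,
pct_change``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import SlopeSeries
from .electrics import PulseRecord
from .errors import SchemaError

__all__ = ["read_raw", "write_raw", "read_slopes", "write_slopes"]

RAW_COLUMNS = ["pulse_index", "onset_s", "current_A", "t_rel_s", "voltage_V"]
SLOPE_COLUMNS = ["pulse_index", "t_h", "slope", "intercept", "r2", "pct_change"]


def write_raw(path, records) -> None:
    """Serialise pulse records to the raw-pulse CSV schema."""
    frames = []
    for rec in records:
        frames.append(
            pd.DataFrame(
                {
                    "pulse_index": rec.pulse_index,
                    "onset_s": rec.onset,
                    "current_A": rec.current,
                    "t_rel_s": rec.t_rel,
                    "voltage_V": rec.voltage,
                }
            )
        )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame({c: [] for c in RAW_COLUMNS})
    table.to_csv(path, index=False, float_format="%.10g")


def read_raw(path) -> list[PulseRecord]:
    """Parse a raw-pulse CSV, validating the schema.

    Raises :class:`SchemaError` (naming the offending row where
    applicable) on missing columns, unsorted/duplicate rows, or a
    current that varies within a pulse.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in RAW_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if table.empty:
        return []
    key = list(zip(table["pulse_index"], table["t_rel_s"]))
    for row in range(1, len(key)):
        if key[row] <= key[row - 1]:
            raise SchemaError(
                f"{path}: rows not sorted/unique by (pulse_index, t_rel_s) at row {row + 2}"
            )
    records = []
    for idx, group in table.groupby("pulse_index", sort=True):
        currents = group["current_A"].to_numpy()
        if np.ptp(currents) != 0.0:
            row = int(group.index[np.nonzero(currents != currents[0])[0][0]])
            raise SchemaError(
                f"{path}: current varies within pulse {idx} (first at row {row + 2})"
            )
        onsets = group["onset_s"].to_numpy()
        if np.ptp(onsets) != 0.0:
            raise SchemaError(f"{path}: onset varies within pulse {idx}")
        records.append(
            PulseRecord(
                pulse_index=int(idx),
                onset=float(onsets[0]),
                current=float(currents[0]),
                t_rel=group["t_rel_s"].to_numpy(dtype=float),
                voltage=group["voltage_V"].to_numpy(dtype=float),
            )
        )
    return records


def write_slopes(path, series: SlopeSeries) -> None:
    """Serialise a slope series to CSV."""
    series.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_slopes(path) -> SlopeSeries:
    """Parse a slope-series CSV back into a :class:`SlopeSeries`."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in SLOPE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return SlopeSeries(
        pulse_index=table["pulse_index"].to_numpy(dtype=int),
        t_h=table["t_h"].to_numpy(dtype=float),
        slope=table["slope"].to_numpy(dtype=float),
        intercept=table["intercept"].to_numpy(dtype=float),
        r2=table["r2"].to_numpy(dtype=float),
        pct_change=table["pct_change"].to_numpy(dtype=float),
    )
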