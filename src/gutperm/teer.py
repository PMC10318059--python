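"""TEER barrier-index computation and two-stage normalization.

Impedance of an epithelial monolayer at low frequency (1 kHz) is dominated
by the paracellular path while the high-frequency (41 kHz) signal is not,
so the ratio z_1kHz / z_41kHz — the barrier index — tracks junctional
integrity independently of electrode drift. Traces are normalized to their
own t=0 baseline and then corrected by the same-normalized mean of the
unstimulated control wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def barrier_index(z_1khz: float, z_41khz: float) -> float:
    """Low/high-frequency impedance ratio; both impedances must be positive."""
    if z_1khz <= 0 or z_41khz <= 0:
        raise ValueError("impedances must be positive")
    return z_1khz / z_41khz


@dataclass
class BarrierIndexTrace:
    """Barrier index of one well over time, optionally control-corrected."""

    well: str
    condition: str
    times_min: np.ndarray
    barrier_index: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.barrier_index = np.asarray(self.barrier_index, dtype=float)
        if self.times_min.shape != self.barrier_index.shape:
            raise ValueError("times and barrier index must have equal length")
        if np.any(self.barrier_index <= 0):
            raise ValueError("barrier index must be positive")

    @property
    def self_normalized(self) -> np.ndarray:
        """Trace divided by its own t=0 value (first element exactly 1)."""
        return self.barrier_index / self.barrier_index[0]


def traces_from_table(df: pd.DataFrame) -> list[BarrierIndexTrace]:
    """One BarrierIndexTrace per well from a two-frequency impedance table."""
    required = {"time_min", "well", "z_1khz_ohm", "z_41khz_ohm", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TEER table missing columns: {sorted(missing)}")
    if (df["z_1khz_ohm"] <= 0).any() or (df["z_41khz_ohm"] <= 0).any():
        raise ValueError("impedances must be positive")
    traces = []
    for well, g in df.groupby("well", sort=True):
        g = g.sort_values("time_min")
        conditions = g["condition"].unique()
        if len(conditions) != 1:
            raise ValueError(f"well {well} has multiple condition labels")
        traces.append(
            BarrierIndexTrace(
                well=str(well),
                condition=str(conditions[0]),
                times_min=g["time_min"].to_numpy(),
                barrier_index=(g["z_1khz_ohm"] / g["z_41khz_ohm"]).to_numpy(),
            )
        )
    return traces


def control_reference(ctrl_traces: list[BarrierIndexTrace]) -> np.ndarray:
    """Per-timestamp mean of the self-normalized unstimulated-control traces."""
    if not ctrl_traces:
        raise ValueError("no control traces")
    t0 = ctrl_traces[0].times_min
    for tr in ctrl_traces[1:]:
        if not np.array_equal(tr.times_min, t0):
            raise ValueError("control traces have mismatched timestamps")
    return np.mean([tr.self_normalized for tr in ctrl_traces], axis=0)


def normalize_barrier(
    trace: BarrierIndexTrace,
    ctrl: BarrierIndexTrace | list[BarrierIndexTrace],
) -> BarrierIndexTrace:
    """Two-stage normalization: own t=0 baseline, then the control reference.

    Timestamps must match exactly (the instrument exports a regular grid);
    no resampling is attempted.
    """
    ctrl_traces = [ctrl] if isinstance(ctrl, BarrierIndexTrace) else list(ctrl)
    for tr in ctrl_traces:
        if not np.array_equal(tr.times_min, trace.times_min):
            raise ValueError("timestamp mismatch between trace and control")
    reference = control_reference(ctrl_traces)
    normalized = trace.self_normalized / reference
    return BarrierIndexTrace(
        well=trace.well,
        condition=trace.condition,
        times_min=trace.times_min,
        barrier_index=trace.barrier_index,
        normalized=normalized,
    )


def normalize_table(df: pd.DataFrame, control_condition: str = "unstimulated") -> pd.DataFrame:
    """Normalize every well in a table against the unstimulated wells.

    Returns a tidy frame (time_min, well, condition, barrier_index,
    normalized); control wells are normalized against the control mean too,
    so their average normalized trace is 1 by construction.
    """
    traces = traces_from_table(df)
    ctrl = [t for t in traces if t.condition == control_condition]
    if not ctrl:
        raise ValueError(f"no wells with control condition {control_condition!r}")
    rows = []
    for tr in traces:
        norm = normalize_barrier(tr, ctrl)
        rows.append(
            pd.DataFrame(
                {
                    "time_min": tr.times_min,
                    "well": tr.well,
                    "condition": tr.condition,
                    "barrier_index": tr.barrier_index,
                    "normalized": norm.normalized,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
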