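"""OD600 growth curves: percent inhibition and screening-dose selection.

Inhibition is the relative loss of growth area: 100 * (1 - AUC_t / AUC_c),
where AUC is the trapezoidal area under the baseline-subtracted curve
(od - od[0], clipped at 0).  The screening dose is the one whose inhibition
falls in the 10-20% band, closest to the top of the band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GrowthCurve", "percent_inhibition", "select_dose", "read_od_table"]


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time course; times in minutes, strictly increasing."""

    times: np.ndarray
    od: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have matching lengths")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.od < 0).any():
            raise ValueError("OD readings must be >= 0")

    def auc(self) -> float:
        """Trapezoidal area of the baseline-subtracted curve, clipped at 0."""
        growth = np.clip(self.od - self.od[0], 0.0, None)
        return float(np.trapezoid(growth, self.times))


def percent_inhibition(control: GrowthCurve, treated: GrowthCurve) -> float:
    """100 * (1 - AUC_treated / AUC_control); may be negative for
    faster-than-control growth, at most 100 for no growth."""
    if control.times.shape != treated.times.shape or not np.array_equal(
        control.times, treated.times
    ):
        raise ValueError("control and treated curves must share the time grid")
    auc_c = control.auc()
    if auc_c <= 0:
        raise ValueError("control curve shows no growth (AUC <= 0)")
    return 100.0 * (1.0 - treated.auc() / auc_c)


def select_dose(
    series: Sequence[tuple[float, GrowthCurve]],
    control: GrowthCurve,
    lo: float = 10.0,
    hi: float = 20.0,
) -> float | None:
    """Pick the screening dose from a dilution series.

    Among doses whose inhibition lies in [lo, hi], return the one closest to
    ``hi`` (ties -> lower dose); None when no dose lands in the band.
    """
    if not series:
        raise ValueError("empty dose series")
    doses = [d for d, _ in series]
    if len(set(doses)) != len(doses) or any(d <= 0 for d in doses):
        raise ValueError("doses must be positive and distinct")
    in_band = []
    for dose, curve in series:
        inhibition = percent_inhibition(control, curve)
        if lo <= inhibition <= hi:
            in_band.append((abs(hi - inhibition), dose))
    if not in_band:
        return None
    return min(in_band)[1]


def read_od_table(path: str | Path, time_column: str = "time_min") -> dict[str, GrowthCurve]:
    """Read a TSV with a time column plus one OD column per well."""
    frame = pd.read_csv(path, sep="\t")
    if time_column not in frame.columns:
        raise ValueError(f"missing time column {time_column!r}")
    times = frame[time_column].to_numpy(dtype=float)
    return {
        col: GrowthCurve(times=times, od=frame[col].to_numpy(dtype=float), label=col)
        for col in frame.columns
        if col != time_column
    }
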