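"""Stability-threshold alarms on the 7-day change-probability series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AlarmSeries", "detect_alarms", "DEFAULT_BURN_IN"]

#: Days at the start of each record excluded from alarming/evaluation:
#: the windowed change probability saturates at 1 there by construction.
DEFAULT_BURN_IN = 7


@dataclass
class AlarmSeries:
    """Per-day alarms for one patient at a fixed stability threshold.

    ``alarm[d]`` is ``probability[d] > threshold`` on evaluable days and
    ``False`` during burn-in; ``evaluable`` marks days past burn-in.
    """

    alarm: np.ndarray
    threshold: float
    burn_in: int
    evaluable: np.ndarray

    @property
    def n_days(self) -> int:
        return len(self.alarm)

    def alarm_days(self) -> np.ndarray:
        return np.flatnonzero(self.alarm)


def detect_alarms(series, threshold: float, burn_in: int = DEFAULT_BURN_IN) -> AlarmSeries:
    """Strict-exceedance thresholding of the change-probability series.

    ``threshold`` must lie in the open interval (0, 1).  Lowering the
    threshold can only add alarm days, never remove them.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"stability threshold must be in (0, 1), got {threshold}")
    p = np.asarray(series, dtype=float)
    evaluable = np.arange(len(p)) >= burn_in
    alarm = (p > threshold) & evaluable
    return AlarmSeries(alarm=alarm, threshold=float(threshold),
                       burn_in=int(burn_in), evaluable=evaluable)
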