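"""Analysis-window catalog.

Every windowed statistic in the pipeline is computed on a named half-open
window ``[anchor + start, anchor + end)`` in integer ms.  Printed window
bounds such as "201-400 ms" denote 200 ms of data at 1-kHz sampling, which
under the half-open integer convention is ``[201, 401)``; the same
convention is applied to every catalog entry so durations are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ANCHORS = ("tc_onset", "cs_onset", "trace_onset", "outcome_time")


@dataclass(frozen=True)
class WindowDef:
    name: str
    anchor: str
    start: int  # ms offset, inclusive
    end: int    # ms offset, exclusive

    def __post_init__(self) -> None:
        if self.anchor not in ANCHORS:
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.end <= self.start:
            raise ValueError(f"window {self.name}: end must exceed start")

    @property
    def duration_ms(self) -> int:
        return self.end - self.start

    def resolve(self, trials: pd.DataFrame):
        """Absolute (starts, ends) per trial; NaN where the anchor is absent
        (e.g. CS-anchored windows on uncued trials)."""
        anchor = trials[self.anchor].to_numpy(dtype=float)
        return anchor + self.start, anchor + self.end


#: the standard windows: pre-outcome behaviour epoch, pre-TC baselines,
#: TC and CS/US test windows, and the late-trace uncertainty epochs
WINDOW_CATALOG = {
    w.name: w for w in [
        WindowDef("behavior", "outcome_time", -250, 0),
        WindowDef("z_baseline", "tc_onset", -500, 0),
        WindowDef("context_baseline", "tc_onset", -1000, 0),
        WindowDef("tc", "tc_onset", 101, 501),
        WindowDef("cs_test", "cs_onset", 201, 401),
        WindowDef("us_test", "outcome_time", 201, 401),
        WindowDef("trace_uncertainty", "outcome_time", -500, 0),
        WindowDef("trace_late", "outcome_time", -400, 0),
    ]
}


def get_window(window) -> WindowDef:
    if isinstance(window, WindowDef):
        return window
    try:
        return WINDOW_CATALOG[window]
    except KeyError:
        raise KeyError(
            f"unknown window {window!r}; catalog: {sorted(WINDOW_CATALOG)}"
        ) from None
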