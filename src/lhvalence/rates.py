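"""Windowed firing rates, baseline-normalised PSTHs and ROC-AUC indices."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import Dataset
from .windows import WindowDef, get_window

TrialFilter = Union[None, str, Sequence[bool], Callable[[pd.DataFrame], Sequence[bool]]]


def count_rate(spikes, start_ms: float, end_ms: float,
               trial_end: Optional[float] = None) -> float:
    """Firing rate (Hz) in the half-open window ``[start_ms, end_ms)``.

    A spike exactly at ``end_ms`` is excluded.  ``trial_end`` optionally
    enables a bounds check on the window itself.
    """
    if end_ms <= start_ms:
        raise ValueError("window end must exceed start")
    if start_ms < 0 or (trial_end is not None and end_ms > trial_end):
        raise ValueError(
            f"window [{start_ms}, {end_ms}) outside trial span")
    s = np.asarray(spikes)
    n = int(np.count_nonzero((s >= start_ms) & (s < end_ms)))
    return n / ((end_ms - start_ms) / 1000.0)


@dataclass
class RateTable:
    """Firing rates (Hz) for one window: neurons x selected trials."""

    window: WindowDef
    neuron_ids: List[str]
    trials: pd.DataFrame          # metadata of the selected trials, in order
    rates: np.ndarray             # (n_neurons, n_trials)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, index=self.neuron_ids,
                          columns=self.trials["trial_id"])
        df.index.name = "neuron_id"
        return df


def _resolve_filter(trials: pd.DataFrame, trial_filter: TrialFilter) -> np.ndarray:
    if trial_filter is None:
        mask = np.ones(len(trials), dtype=bool)
    elif isinstance(trial_filter, str):
        mask = trials.eval(trial_filter).to_numpy(dtype=bool)
    elif callable(trial_filter):
        mask = np.asarray(trial_filter(trials), dtype=bool)
    else:
        mask = np.asarray(trial_filter, dtype=bool)
    if not mask.any():
        raise ValueError(f"trial filter {trial_filter!r} selects no trials")
    return mask


def build_rate_table(dataset: Dataset, window,
                     trial_filter: TrialFilter = None) -> RateTable:
    """Rates for every neuron on every trial matched by ``trial_filter``.

    Trials whose window anchor is undefined (CS-anchored windows on uncued
    trials) raise unless the filter excludes them.
    """
    win = get_window(window)
    mask = _resolve_filter(dataset.trials, trial_filter)
    sel = dataset.trials.loc[mask].reset_index(drop=True)
    starts, ends = win.resolve(sel)
    if np.isnan(starts).any():
        bad = sel.loc[np.isnan(starts), "trial_id"].tolist()[:3]
        raise ValueError(
            f"window {win.name!r} anchored at {win.anchor!r} is undefined "
            f"for selected trial(s) {bad}; filter them out")
    if (starts < 0).any() or (ends > sel["trial_end"].to_numpy()).any():
        raise ValueError(f"window {win.name!r} outside trial span")

    neuron_ids = dataset.neuron_ids
    rates = np.empty((len(neuron_ids), len(sel)))
    dur_s = win.duration_ms / 1000.0
    for i, nid in enumerate(neuron_ids):
        nr = dataset.neurons[nid]
        idx = np.array([nr._index[t] for t in sel["trial_id"]])
        rates[i] = nr.window_counts(idx, starts, ends) / dur_s
    return RateTable(win, neuron_ids, sel, rates)


def window_grid_rates(dataset: Dataset, anchor: str, starts,
                      win_ms: int, trial_filter: TrialFilter = None):
    """Rates on a grid of same-length windows for every neuron.

    Returns ``(rates, trials)`` where ``rates`` has shape
    (n_neurons, n_windows, n_trials) and ``starts`` are ms offsets from
    ``anchor``.  One vectorised count per neuron, so sliding-window
    analyses stay cheap.
    """
    mask = _resolve_filter(dataset.trials, trial_filter)
    sel = dataset.trials.loc[mask].reset_index(drop=True)
    anchors = sel[anchor].to_numpy(dtype=float)
    if np.isnan(anchors).any():
        bad = sel.loc[np.isnan(anchors), "trial_id"].tolist()[:3]
        raise ValueError(f"anchor {anchor!r} undefined for trial(s) {bad}")
    starts = np.asarray(starts, dtype=np.int64)
    abs_starts = anchors[None, :].astype(np.int64) + starts[:, None]
    abs_ends = abs_starts + win_ms
    if abs_starts.min() < 0 or (abs_ends.max(axis=0)
                                > sel["trial_end"].to_numpy()).any():
        raise ValueError("window grid outside trial span")
    neuron_ids = dataset.neuron_ids
    out = np.empty((len(neuron_ids), starts.size, len(sel)))
    dur_s = win_ms / 1000.0
    for i, nid in enumerate(neuron_ids):
        nr = dataset.neurons[nid]
        idx = np.array([nr._index[t] for t in sel["trial_id"]])
        out[i] = nr.window_counts(idx[None, :], abs_starts, abs_ends) / dur_s
    return out, sel


@dataclass
class ZScoredPSTH:
    """Per-block, per-neuron binned rates z-scored by the pre-TC baseline.

    ``z[context]`` has shape (n_neurons, n_bins); neurons whose baseline SD
    is zero in a block and whose activity departs from the baseline mean are
    flagged degenerate and masked (NaN) for that block.
    """

    bin_ms: int
    step_ms: int
    bin_starts: np.ndarray        # ms from CS onset
    neuron_ids: List[str]
    z: Dict[str, np.ndarray]
    degenerate: Dict[str, np.ndarray]  # boolean per neuron per block


def n_sliding_windows(span_ms: int, win_ms: int, step_ms: int) -> int:
    """Number of sliding windows fully inside a span: floor((span-win)/step)+1."""
    if win_ms > span_ms:
        return 0
    return (span_ms - win_ms) // step_ms + 1


def zscore_psth(dataset: Dataset, bin_ms: int = 200, step_ms: int = 50,
                span_ms: Optional[int] = None,
                trial_filter: TrialFilter = "kind == 'cued'") -> ZScoredPSTH:
    """Binned mean rates from CS onset, z-scored per neuron per block.

    The normaliser is the mean and across-trial SD of each neuron's firing
    rate in the last 500 ms before TC onset within the same block.
    """
    cfg = dataset.config
    if span_ms is None:
        span_ms = cfg.cs_duration + cfg.trace_duration
    nbin = n_sliding_windows(span_ms, bin_ms, step_ms)
    bin_starts = np.arange(nbin) * step_ms
    neuron_ids = dataset.neuron_ids
    contexts = list(dict.fromkeys(dataset.trials["context"]))

    z: Dict[str, np.ndarray] = {}
    degenerate: Dict[str, np.ndarray] = {}
    base_win = get_window("z_baseline")
    for ctx in contexts:
        filt = f"context == '{ctx}' and ({trial_filter})" if trial_filter else f"context == '{ctx}'"
        base = build_rate_table(dataset, base_win, filt)
        mu = base.rates.mean(axis=1)
        sd = base.rates.std(axis=1, ddof=0)

        grid, _ = window_grid_rates(dataset, "cs_onset", bin_starts, bin_ms,
                                    filt)
        binned = grid.mean(axis=2)

        zmat = np.empty_like(binned)
        deg = np.zeros(len(neuron_ids), dtype=bool)
        ok = sd > 0
        zmat[ok] = (binned[ok] - mu[ok, None]) / sd[ok, None]
        for i in np.flatnonzero(~ok):
            same = np.isclose(binned[i], mu[i])
            zmat[i] = np.where(same, 0.0, np.nan)
            if not same.all():
                deg[i] = True
        z[ctx] = zmat
        degenerate[ctx] = deg
    return ZScoredPSTH(bin_ms, step_ms, bin_starts, neuron_ids, z, degenerate)


def roc_auc_index(test_rates, baseline_rates) -> float:
    """P(random test rate > random baseline rate), ties counted 1/2.

    Equivalent to the normalised Mann-Whitney U statistic; 0.5 means no
    discrimination, 1.0 full separation above baseline.
    """
    a = np.asarray(test_rates, dtype=float)
    b = np.asarray(baseline_rates, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))
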