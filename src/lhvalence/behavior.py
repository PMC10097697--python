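"""Behavioural valuation statistics.

Anticipatory licking indexes positive (approach) valuation of a CS and
anticipatory blinking negative (avoidance) valuation.  Both are measured
in the last 250 ms before outcome delivery and normalised per recording
session as X/Max, where Max is the session's maximum trial rate for that
measure.  The probability ladder is tested with pairwise Wilcoxon
signed-rank tests over session condition means (Bonferroni over the three
pairs), and the attenuation of blinking in the bivalent relative to the
aversive context with a trial-level two-way ANOVA
(probability x context).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .config import airpuff_probability
from .dataset import Dataset
from .windows import get_window

DEFAULT_ALPHA = 0.05


def normalize_behavior(dataset: Dataset,
                       window: str = "behavior") -> pd.DataFrame:
    """Per-trial normalised lick and blink frequencies joined to metadata.

    A measure with no events anywhere in a session is marked unavailable
    (NaN) for that session.  Values are in [0, 1]; the session's maximum
    trial maps to exactly 1.
    """
    if dataset.behavior is None or not len(dataset.behavior):
        raise ValueError("behavior not available in this dataset")
    win = get_window(window)
    trials = dataset.trials.copy()
    starts, ends = win.resolve(trials)
    bounds = pd.DataFrame({"trial_id": trials["trial_id"],
                           "w0": starts, "w1": ends})
    beh = dataset.behavior.merge(bounds, on="trial_id")
    inwin = beh[(beh["t_ms"] >= beh["w0"]) & (beh["t_ms"] < beh["w1"])]
    dur_s = win.duration_ms / 1000.0
    counts = (inwin.groupby(["trial_id", "event"]).size()
              .unstack(fill_value=0)
              .reindex(trials["trial_id"], fill_value=0)
              .reindex(columns=["lick", "blink"], fill_value=0))
    out = trials[["trial_id", "session_id", "block_index", "context", "kind",
                  "cs_probability", "uncued_type"]].copy()
    out["airpuff_probability"] = [
        airpuff_probability(c, p) if np.isfinite(p) else np.nan
        for c, p in zip(out["context"], out["cs_probability"])]
    for measure in ("lick", "blink"):
        rate = counts[measure].to_numpy(dtype=float) / dur_s
        norm = np.full(len(out), np.nan)
        for sid, idx in out.groupby("session_id").groups.items():
            mx = rate[np.asarray(idx)].max()
            if mx > 0:
                norm[np.asarray(idx)] = rate[np.asarray(idx)] / mx
        out[f"{measure}_rate_hz"] = rate
        out[f"{measure}_norm"] = norm
    return out


def probability_ladder_tests(normalized: pd.DataFrame, context: str,
                             measure: str,
                             alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Pairwise signed-rank tests over the three CS probability levels.

    Observations are session-level condition means (the natural pairing
    unit); identical paired samples give p = 1 by convention.  The
    significance flag applies Bonferroni over the three pairs.
    """
    col = f"{measure}_norm"
    # the blink ladder runs over airpuff probability (reversed relative to
    # the stated reward probabilities in bivalent blocks)
    ladder = "airpuff_probability" if measure == "blink" else "cs_probability"
    sub = normalized[(normalized["context"] == context)
                     & (normalized["kind"] == "cued")].dropna(subset=[col])
    if sub.empty:
        raise ValueError(f"{measure} not available in context {context!r}")
    means = (sub.groupby(["session_id", ladder])[col]
             .mean().unstack())
    levels = sorted(means.columns, reverse=True)
    missing = {1.0, 0.5, 0.0} - set(levels)
    if missing:
        raise ValueError(f"missing probability level(s) {sorted(missing)}")
    rows = []
    for a, b in combinations(levels, 2):
        d = (means[a] - means[b]).dropna().to_numpy()
        if np.allclose(d, 0):
            w, p = 0.0, 1.0
        else:
            w, p = stats.wilcoxon(d)
        rows.append({"context": context, "measure": measure,
                     "level_a": a, "level_b": b, "n_sessions": d.size,
                     "mean_diff": float(np.mean(d)), "statistic": w,
                     "p": p, "significant": p < alpha / 3})
    return pd.DataFrame(rows)


def blink_context_anova(normalized: pd.DataFrame,
                        contexts: Sequence[str] = ("aversive", "bivalent"),
                        ) -> pd.DataFrame:
    """Two-way ANOVA of normalised blink frequency: airpuff probability x
    context, over trial-level observations in the two airpuff contexts."""
    sub = normalized[(normalized["context"].isin(contexts))
                     & (normalized["kind"] == "cued")].dropna(
                         subset=["blink_norm"]).copy()
    cells = sub.groupby(["context", "airpuff_probability"]).size()
    expected = [(c, p) for c in contexts for p in (1.0, 0.5, 0.0)]
    for cell in expected:
        if cell not in cells.index or cells[cell] == 0:
            raise ValueError(f"empty design cell {cell}")
    model = smf.ols(
        "blink_norm ~ C(airpuff_probability) * C(context)", data=sub).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={
        "C(airpuff_probability)": "probability",
        "C(context)": "context",
        "C(airpuff_probability):C(context)": "interaction",
        "Residual": "residual"})
    return table


class BehaviorModel:
    """Fit the behavioural valuation battery of a dataset."""

    def __init__(self, dataset: Dataset, alpha: float = DEFAULT_ALPHA):
        self.dataset = dataset
        self.alpha = alpha

    def fit(self) -> "BehaviorResults":
        norm = normalize_behavior(self.dataset)
        ladders = []
        for ctx, measure in (("appetitive", "lick"), ("bivalent", "lick"),
                             ("aversive", "blink"), ("bivalent", "blink")):
            try:
                ladders.append(probability_ladder_tests(
                    norm, ctx, measure, self.alpha))
            except ValueError:
                pass  # measure unavailable in this dataset
        ladder = (pd.concat(ladders, ignore_index=True)
                  if ladders else pd.DataFrame())
        try:
            anova = blink_context_anova(norm)
        except ValueError:
            anova = None
        return BehaviorResults(self, norm, ladder, anova)


@dataclass
class BehaviorResults:
    model: "BehaviorModel"
    normalized: pd.DataFrame
    ladder_tests: pd.DataFrame
    blink_anova: Optional[pd.DataFrame]

    def summary(self) -> str:
        lines = ["Behavioural valuation"]
        for row in self.ladder_tests.itertuples():
            star = "*" if row.significant else " "
            lines.append(
                f"  {row.context:10s} {row.measure:5s} "
                f"{row.level_a:.0%} vs {row.level_b:.0%}: "
                f"diff={row.mean_diff:+.3f} p={row.p:.3g} {star}")
        if self.blink_anova is not None:
            f = self.blink_anova.loc["context", "F"]
            p = self.blink_anova.loc["context", "PR(>F)"]
            lines.append(f"  blink context effect (aversive vs bivalent): "
                         f"F={f:.1f}, p={p:.3g}")
        else:
            lines.append("  blink context ANOVA: not available")
        return "\n".join(lines)
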