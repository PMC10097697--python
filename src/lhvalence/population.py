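"""Population-level analyses.

* block-wise comparison of the normalised population PSTH (per-bin one-way
  ANOVA with Tukey-Kramer post-hocs),
* sliding-window cross-block correlation of per-neuron sensitivity,
* PCA state-space trajectories of condition-averaged population vectors,
* context modulation of baseline and timing-cue activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .config import airpuff_probability
from .dataset import Dataset
from .rates import (
    build_rate_table,
    n_sliding_windows,
    window_grid_rates,
    zscore_psth,
)
from .tuning import _FAMILY_SPEC, pearson_with_p
from .windows import WindowDef, get_window

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# block-wise population PSTH comparison

def population_block_comparison(dataset: Dataset, bin_ms: int = 200,
                                step_ms: int = 50,
                                alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-bin one-way ANOVA of z-scored population activity across blocks.

    Each neuron contributes its mean z-scored rate per bin per block; bins
    run from CS onset to the end of the trace period.  Pairwise
    Tukey-Kramer flags report which block pairs differ and in which
    direction.  Degenerate-baseline neurons are excluded per block.
    Returns one row per bin plus a ``span`` column marking membership in a
    contiguous run of significant bins.
    """
    psth = zscore_psth(dataset, bin_ms=bin_ms, step_ms=step_ms)
    contexts = list(psth.z)
    rows = []
    for b, start in enumerate(psth.bin_starts):
        samples = []
        for ctx in contexts:
            v = psth.z[ctx][:, b]
            samples.append(v[np.isfinite(v)])
        F, p = stats.f_oneway(*samples)
        row = {"bin_start": int(start), "bin_end": int(start) + bin_ms,
               "F": F, "p": p, "significant": p < alpha}
        if len(contexts) > 1:
            vals = np.concatenate(samples)
            grp = np.concatenate([[c] * len(s)
                                  for c, s in zip(contexts, samples)])
            tk = pairwise_tukeyhsd(vals, grp, alpha=alpha)
            pairs = [(tk.groupsunique[i], tk.groupsunique[j])
                     for i in range(len(tk.groupsunique))
                     for j in range(i + 1, len(tk.groupsunique))]
            for (g1, g2), reject, md in zip(pairs, tk.reject, tk.meandiffs):
                key = f"{g1}_vs_{g2}"
                row[f"tukey_{key}"] = bool(reject)
                row[f"diff_{key}"] = float(md)  # mean(g2) - mean(g1)
        rows.append(row)
    out = pd.DataFrame(rows)
    # contiguous significant spans
    span_id = np.zeros(len(out), dtype=int)
    cur = 0
    for i, sig in enumerate(out["significant"]):
        if sig:
            if i == 0 or not out["significant"].iloc[i - 1]:
                cur += 1
            span_id[i] = cur
    out["span"] = span_id
    return out


# ---------------------------------------------------------------------------
# sliding cross-block sensitivity correlation

@dataclass
class SlidingCorrelationSeries:
    """Cross-neuron Spearman correlation of per-neuron sensitivity between
    two blocks, as a function of sliding-window position."""

    family: str
    block_pair: Tuple[str, str]
    win_ms: int
    step_ms: int
    window_starts: np.ndarray       # ms relative to the family's anchor
    rho: np.ndarray
    p: np.ndarray
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window_start": self.window_starts,
                             "rho": self.rho, "p": self.p,
                             "significant": self.significant})


def _sensitivity_per_window(dataset: Dataset, family: str, block: str,
                            anchor: str, starts: np.ndarray,
                            win_ms: int) -> np.ndarray:
    """Per-neuron correlation r recomputed on each sliding window's rates.

    Returns (n_windows, n_neurons).
    """
    _, builder, kw = _FAMILY_SPEC[family]
    if family == "predictability" and block == "aversive":
        # the aversive block's US is the airpuff; its predictability ladder
        # is the one a neuron recorded there could express
        kw = {"us": "airpuff"}
    mask, x = builder(dataset.trials, block, **kw)
    if mask.sum() == 0 or np.unique(x).size < 2:
        return np.full((len(starts), len(dataset.neurons)), np.nan)
    grid, _ = window_grid_rates(dataset, anchor, starts, win_ms,
                                mask.to_numpy())
    out = np.empty((len(starts), len(dataset.neurons)))
    for j in range(grid.shape[0]):                 # per neuron
        r, _ = pearson_with_p(x, grid[j])
        out[:, j] = r
    return out


def crossblock_sensitivity_series(
        dataset: Dataset, block_pair: Tuple[str, str] = ("appetitive", "bivalent"),
        family: str = "cs_value", win_ms: int = 200, step_ms: int = 10,
        span_ms: Optional[int] = None,
        alpha: float = DEFAULT_ALPHA) -> SlidingCorrelationSeries:
    """Sliding-window correlation of tuning between two blocks.

    In each window every neuron's within-block sensitivity (correlation of
    rate with the family's task variable) is recomputed on that window's
    rates, then the two blocks' sensitivity vectors are compared across all
    neurons with Spearman's rho.  CS-value windows slide from CS onset over
    the CS + trace epoch; predictability windows slide from outcome
    delivery over the post-outcome epoch.
    """
    cfg = dataset.config
    if family in ("cs_value", "punishment_value"):
        anchor = "cs_onset"
        default_span = cfg.cs_duration + cfg.trace_duration
    else:
        anchor = "outcome_time"
        default_span = cfg.outcome_duration + cfg.post_outcome_ms
    span = span_ms if span_ms is not None else default_span
    n_win = n_sliding_windows(span, win_ms, step_ms)
    if n_win <= 0:
        raise ValueError(
            f"window {win_ms} ms exceeds the {span} ms analysis span")
    starts = np.arange(n_win) * step_ms

    sens = {blk: _sensitivity_per_window(dataset, family, blk, anchor,
                                         starts, win_ms)
            for blk in block_pair}
    rho = np.empty(n_win)
    p = np.empty(n_win)
    a, b = block_pair
    for i in range(n_win):
        va, vb = sens[a][i], sens[b][i]
        ok = np.isfinite(va) & np.isfinite(vb)
        if ok.sum() < 3:
            rho[i], p[i] = np.nan, np.nan
        else:
            rho[i], p[i] = stats.spearmanr(va[ok], vb[ok])
    return SlidingCorrelationSeries(family, tuple(block_pair), win_ms,
                                    step_ms, starts, rho, p, alpha)


# ---------------------------------------------------------------------------
# PCA state space

@dataclass
class PCAResult:
    """PCA of condition-averaged population activity.

    The training matrix stacks, for each (block, trial type), the
    population vector (one mean firing rate per neuron) of every time bin;
    PCA is fit over these bin-vectors with per-neuron mean centering, so a
    trajectory is a condition's sequence of bins in PC space.
    """

    loadings: np.ndarray            # (n_components, n_neurons)
    explained_variance_ratio: np.ndarray
    bin_starts: np.ndarray          # ms from CS onset
    conditions: List[Tuple[str, float]]
    trajectories: Dict[Tuple[str, float], np.ndarray]  # (n_bins, n_comp)
    mean_: np.ndarray               # per-neuron training mean
    effective_rank: int
    neuron_ids: List[str]

    def project(self, vectors: np.ndarray) -> np.ndarray:
        """Project held-out population vectors (rows = conditions, columns
        = neurons) with the training centering and loadings."""
        V = np.atleast_2d(np.asarray(vectors, dtype=float))
        return (V - self.mean_) @ self.loadings.T

    def trajectory_frame(self) -> pd.DataFrame:
        rows = []
        for (blk, p), traj in self.trajectories.items():
            for b, (t, xy) in enumerate(zip(self.bin_starts, traj)):
                rows.append({"block": blk, "cs_probability": p,
                             "bin_start": int(t),
                             **{f"pc{i+1}": v for i, v in enumerate(xy)}})
        return pd.DataFrame(rows)


def pca_state_space(dataset: Dataset, bin_ms: int = 100,
                    trial_probs: Sequence[float] = (1.0, 0.0),
                    blocks: Sequence[str] = ("appetitive", "bivalent",
                                             "aversive"),
                    n_components: Optional[int] = None) -> PCAResult:
    """Fit the population state space from CS-onset-aligned averaged rates.

    The matrix concatenates non-overlapping ``bin_ms`` bins from CS onset
    to the end of the trace for each block x trial-type condition.
    """
    cfg = dataset.config
    span = cfg.cs_duration + cfg.trace_duration
    nbin = span // bin_ms
    bin_starts = np.arange(nbin) * bin_ms
    neuron_ids = dataset.neuron_ids

    conditions = [(blk, p) for blk in blocks for p in trial_probs]
    cols = []
    for blk, p in conditions:
        filt = (f"context == '{blk}' and kind == 'cued' "
                f"and cs_probability == {p}")
        grid, _ = window_grid_rates(dataset, "cs_onset", bin_starts, bin_ms,
                                    filt)
        cols.append(grid.mean(axis=2).T)    # (nbin, n_neurons)
    X = np.concatenate(cols, axis=0)        # (n_cond*nbin, n_neurons)
    n_comp = n_components or min(X.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    eff_rank = int((pca.explained_variance_ > 1e-12).sum())

    trajectories = {}
    for i, cond in enumerate(conditions):
        trajectories[cond] = scores[i * nbin:(i + 1) * nbin]
    return PCAResult(pca.components_, pca.explained_variance_ratio_,
                     bin_starts, conditions, trajectories,
                     pca.mean_, eff_rank, neuron_ids)


def project_outcome_responses(result: PCAResult, dataset: Dataset,
                              window: str = "us_test") -> pd.DataFrame:
    """Project held-out outcome-period population vectors into the space.

    One vector per (block, trial kind/type, delivered outcome): per-neuron
    mean rate in the post-outcome test window, centred with the training
    means and multiplied by the loadings.
    """
    rows = []
    trials = dataset.trials
    groups = trials.groupby(["context", "kind", "uncued_type",
                             "delivered_outcome"], dropna=False)
    for (blk, kind, utype, out), sub in groups:
        mask = trials["trial_id"].isin(sub["trial_id"]).to_numpy()
        rt = build_rate_table(dataset, window, mask)
        vec = rt.rates.mean(axis=1)
        xy = result.project(vec)[0]
        rows.append({"block": blk, "kind": kind,
                     "uncued_type": utype if isinstance(utype, str) else "",
                     "delivered_outcome": out,
                     **{f"pc{i+1}": v for i, v in enumerate(xy[:2])}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# baseline / timing-cue context statistics

def context_modulation_stats(dataset: Dataset, window: str = "context_baseline",
                             alpha: float = DEFAULT_ALPHA) -> dict:
    """Context modulation of a window's rates at cell and population level.

    Per cell: one-way ANOVA of trial rates across the three blocks
    (fraction significant at ``alpha``).  Population: one-way ANOVA across
    blocks of per-neuron block-mean rates.  Pairwise: per-cell Welch
    t-tests per block pair at the Bonferroni-corrected ``alpha/3``.
    """
    present = set(dataset.trials["context"])
    contexts = [c for c in ("appetitive", "aversive", "bivalent")
                if c in present]
    rates = {}
    for ctx in contexts:
        rt = build_rate_table(dataset, window, f"context == '{ctx}'")
        rates[ctx] = rt.rates               # (n_neurons, n_trials)
    n_neurons = len(dataset.neurons)

    per_cell_p = np.empty(n_neurons)
    for i in range(n_neurons):
        per_cell_p[i] = stats.f_oneway(*[rates[c][i] for c in contexts]).pvalue
    frac = float((per_cell_p < alpha).mean())

    block_means = np.array([rates[c].mean(axis=1) for c in contexts])
    F, p = stats.f_oneway(*block_means)

    pair_counts = {}
    pairs = [(a, b) for i, a in enumerate(contexts)
             for b in contexts[i + 1:]]
    for a, b in pairs:
        pv = stats.ttest_ind(rates[a], rates[b], axis=1,
                             equal_var=False).pvalue
        pair_counts[f"{a}_vs_{b}"] = int((pv < alpha / 3).sum())

    return {"window": get_window(window).name,
            "per_cell_fraction": frac,
            "per_cell_pvalues": per_cell_p,
            "population_F": float(F), "population_p": float(p),
            "pairwise_counts": pair_counts}


# ---------------------------------------------------------------------------
# modelling object

class PopulationModel:
    """Run the population analyses of a dataset as one fitted object."""

    def __init__(self, dataset: Dataset, alpha: float = DEFAULT_ALPHA,
                 psth_bin_ms: int = 200, psth_step_ms: int = 50,
                 slide_win_ms: int = 200, slide_step_ms: int = 10,
                 pca_bin_ms: int = 100):
        self.dataset = dataset
        self.alpha = alpha
        self.psth_bin_ms = psth_bin_ms
        self.psth_step_ms = psth_step_ms
        self.slide_win_ms = slide_win_ms
        self.slide_step_ms = slide_step_ms
        self.pca_bin_ms = pca_bin_ms

    def fit(self) -> "PopulationResults":
        block_comparison = population_block_comparison(
            self.dataset, self.psth_bin_ms, self.psth_step_ms, self.alpha)
        series = {}
        for fam in ("cs_value", "predictability"):
            for pair in (("appetitive", "bivalent"),
                         ("aversive", "bivalent"),
                         ("appetitive", "aversive")):
                series[(fam, pair)] = crossblock_sensitivity_series(
                    self.dataset, pair, fam, self.slide_win_ms,
                    self.slide_step_ms, alpha=self.alpha)
        pca = pca_state_space(self.dataset, self.pca_bin_ms)
        ctx = {w: context_modulation_stats(self.dataset, w, self.alpha)
               for w in ("context_baseline", "tc")}
        return PopulationResults(self, block_comparison, series, pca, ctx)


@dataclass
class PopulationResults:
    model: PopulationModel
    block_comparison: pd.DataFrame
    sensitivity_series: Dict[Tuple[str, Tuple[str, str]],
                             SlidingCorrelationSeries]
    pca: PCAResult
    context_stats: Dict[str, dict]

    def summary(self) -> str:
        nsig = int(self.block_comparison["significant"].sum())
        lines = [f"Population analyses "
                 f"(n={len(self.pca.neuron_ids)} neurons)",
                 f"  block PSTH comparison: {nsig}/"
                 f"{len(self.block_comparison)} bins significant"]
        for (fam, pair), s in self.sensitivity_series.items():
            frac = float(np.nanmean(s.significant))
            lines.append(f"  {fam} sensitivity {pair[0]} vs {pair[1]}: "
                         f"median rho={np.nanmedian(s.rho):.2f}, "
                         f"{frac:.0%} windows significant")
        ev = self.pca.explained_variance_ratio[:2]
        lines.append(f"  PCA: PC1 {ev[0]:.0%}, PC2 {ev[1]:.0%} variance")
        for w, st in self.context_stats.items():
            lines.append(f"  {w}: {st['per_cell_fraction']:.0%} cells "
                         f"context-modulated; population F={st['population_F']:.2f} "
                         f"(p={st['population_p']:.2g})")
        return "\n".join(lines)
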