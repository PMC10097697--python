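"""Per-neuron tuning classification.

Each neuron is tested, block by block, for three signal families by
trial-level linear regression of windowed firing rates on a task variable:

* **CS value** — post-CS rates (201-400 ms window) against the CS's
  outcome probability; a positive slope is a "positive type", negative a
  "negative type".
* **Predictability** — post-outcome rates on delivered-US trials against
  how predictable delivery was (cued 100% = 1, cued 50% = 0.5, free = 0);
  negative slopes are "unpredicted-preferring", positive "predicted-
  preferring".
* **Uncertainty** — late-trace rates against the uncertainty indicator
  (50% trials = 1, 100%/0% = 0); positive slopes are "50%-highest"
  (inverted-U), negative "50%-lowest" (U-shaped).

The per-neuron statistic is the OLS slope t-test, reported as (r, p); with
a single predictor it is identical to the Pearson correlation test.
Context types compare a family's significance pattern across two blocks
(appetitive vs bivalent for reward families, aversive vs bivalent for
punishment families): tuned in one block only, in both with the same sign,
or in both with opposite signs ("sign-inconsistent").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import airpuff_probability
from .dataset import Dataset
from .rates import RateTable, build_rate_table, roc_auc_index
from .windows import get_window

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationStat:
    """Trial-level correlation of rate with a task variable in one block."""
    r: float
    p: float
    n: int
    block: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r) and np.isfinite(self.p)


def pearson_with_p(x: np.ndarray, Y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson r and two-sided p of each row of Y against x.

    Rows with zero variance (or a constant x) get (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = x.size
    xc = x - x.mean()
    sx = np.sqrt((xc ** 2).sum())
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sy = np.sqrt((Yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    bad = (sy == 0) | (sx == 0) | (n < 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    r = np.where(bad, np.nan, r)
    p = np.where(bad, np.nan, p)
    return r, p


# ---------------------------------------------------------------------------
# family-specific trial selections and predictors

def _cs_value_selection(trials: pd.DataFrame, block: str,
                        drive: str = "reward") -> Tuple[pd.Series, np.ndarray]:
    mask = (trials["context"] == block) & (trials["kind"] == "cued")
    p = trials.loc[mask, "cs_probability"].to_numpy(dtype=float)
    if drive == "airpuff":
        x = np.array([airpuff_probability(block, v) for v in p])
    else:
        x = p
    return mask, x


def _predictability_selection(trials: pd.DataFrame, block: str,
                              us: str = "reward") -> Tuple[pd.Series, np.ndarray]:
    mask = (trials["context"] == block) & (trials["delivered_outcome"] == us)
    sub = trials.loc[mask]
    x = np.empty(len(sub))
    for i, row in enumerate(sub.itertuples()):
        if row.kind == "uncued":
            x[i] = 0.0
        elif us == "airpuff":
            x[i] = airpuff_probability(block, float(row.cs_probability))
        else:
            x[i] = float(row.cs_probability)
    return mask, x


def _uncertainty_selection(trials: pd.DataFrame,
                           block: str) -> Tuple[pd.Series, np.ndarray]:
    mask = (trials["context"] == block) & (trials["kind"] == "cued")
    p = trials.loc[mask, "cs_probability"].to_numpy(dtype=float)
    return mask, (p == 0.5).astype(float)


_FAMILY_SPEC = {
    # family -> (window name, selection builder, kwargs)
    "cs_value": ("cs_test", _cs_value_selection, {}),
    "punishment_value": ("cs_test", _cs_value_selection, {"drive": "airpuff"}),
    "predictability": ("us_test", _predictability_selection, {"us": "reward"}),
    "punishment_predictability": ("us_test", _predictability_selection,
                                  {"us": "airpuff"}),
    "uncertainty": ("trace_uncertainty", _uncertainty_selection, {}),
}


def family_stats(dataset: Dataset, family: str, block: str,
                 rate_table: Optional[RateTable] = None) -> pd.DataFrame:
    """(r, p, n) for every neuron for one family in one block.

    Returns NaN stats (label "none" downstream) when the predictor has
    fewer than two distinct levels or, for predictability, when any of the
    three levels has no trials.
    """
    window, builder, kw = _FAMILY_SPEC[family]
    mask, x = builder(dataset.trials, block, **kw)
    neuron_ids = dataset.neuron_ids
    nan = pd.DataFrame({"neuron_id": neuron_ids, "r": np.nan, "p": np.nan,
                        "n": int(mask.sum()), "block": block})
    if mask.sum() == 0 or np.unique(x).size < 2:
        return nan
    if "predictability" in family and np.unique(x).size < 3:
        return nan  # a predictability level is empty
    if rate_table is None:
        rate_table = build_rate_table(dataset, window, mask.to_numpy())
    r, p = pearson_with_p(x, rate_table.rates)
    return pd.DataFrame({"neuron_id": neuron_ids, "r": r, "p": p,
                         "n": x.size, "block": block})


def _single(dataset: Dataset, neuron_id: str, family: str,
            block: str) -> CorrelationStat:
    df = family_stats(dataset, family, block)
    row = df.set_index("neuron_id").loc[neuron_id]
    return CorrelationStat(float(row["r"]), float(row["p"]),
                           int(row["n"]), block)


def cs_value_stat(dataset: Dataset, neuron_id: str, block: str,
                  drive: str = "reward") -> CorrelationStat:
    fam = "punishment_value" if drive == "airpuff" else "cs_value"
    return _single(dataset, neuron_id, fam, block)


def predictability_stat(dataset: Dataset, neuron_id: str, block: str,
                        us: str = "reward") -> CorrelationStat:
    fam = "punishment_predictability" if us == "airpuff" else "predictability"
    return _single(dataset, neuron_id, fam, block)


def uncertainty_stat(dataset: Dataset, neuron_id: str,
                     block: str) -> CorrelationStat:
    return _single(dataset, neuron_id, "uncertainty", block)


def assign_context_type(stat_a: CorrelationStat, stat_b: CorrelationStat,
                        alpha: float = DEFAULT_ALPHA,
                        labels: Tuple[str, str, str] = (
                            "appetitive_only", "bivalent_only",
                            "appetitive_bivalent")) -> str:
    """Deterministic context-type mapping from two blocks' statistics.

    Significant in both blocks with equal sign -> the "both" label; with
    opposite signs -> ``sign_inconsistent``; in one block only -> that
    block's label; otherwise ``none``.
    """
    sig_a = stat_a.defined and stat_a.p < alpha
    sig_b = stat_b.defined and stat_b.p < alpha
    if sig_a and sig_b:
        return labels[2] if np.sign(stat_a.r) == np.sign(stat_b.r) \
            else "sign_inconsistent"
    if sig_a:
        return labels[0]
    if sig_b:
        return labels[1]
    return "none"


_SIGN_LABELS = {
    "cs_value": ("positive", "negative"),
    "punishment_value": ("positive", "negative"),
    "predictability": ("predicted_pref", "unpredicted_pref"),
    "punishment_predictability": ("predicted_pref", "unpredicted_pref"),
    "uncertainty": ("highest_50", "lowest_50"),
}


def sign_label(family: str, r: float, p: float,
               alpha: float = DEFAULT_ALPHA) -> str:
    if not (np.isfinite(r) and np.isfinite(p)) or p >= alpha or r == 0:
        return "none"
    pos, neg = _SIGN_LABELS[family]
    return pos if r > 0 else neg


# ---------------------------------------------------------------------------
# modelling objects

_FAMILY_BLOCKS = {
    "cs_value": ("appetitive", "bivalent", "aversive"),
    "predictability": ("appetitive", "bivalent"),
    "uncertainty": ("appetitive", "bivalent", "aversive"),
    "punishment_value": ("aversive", "bivalent"),
    "punishment_predictability": ("aversive", "bivalent"),
}

_CONTEXT_PAIR = {
    # family -> (block A, block B, context labels)
    "cs_value": ("appetitive", "bivalent",
                 ("appetitive_only", "bivalent_only", "appetitive_bivalent")),
    "predictability": ("appetitive", "bivalent",
                       ("appetitive_only", "bivalent_only",
                        "appetitive_bivalent")),
    "uncertainty": ("appetitive", "bivalent",
                    ("appetitive_only", "bivalent_only",
                     "appetitive_bivalent")),
    "punishment_value": ("aversive", "bivalent",
                         ("aversive_only", "bivalent_only",
                          "aversive_bivalent")),
    "punishment_predictability": ("aversive", "bivalent",
                                  ("aversive_only", "bivalent_only",
                                   "aversive_bivalent")),
}


class NeuronTuningModel:
    """Classify every neuron of a dataset into the tuning taxonomy.

    Parameters
    ----------
    dataset : Dataset
    alpha : float
        Per-family, per-block significance criterion (default 0.05).
    families : sequence of str, optional
        Subset of ``{"cs_value", "predictability", "uncertainty",
        "punishment_value", "punishment_predictability"}``.
    """

    def __init__(self, dataset: Dataset, alpha: float = DEFAULT_ALPHA,
                 families: Optional[Sequence[str]] = None):
        self.dataset = dataset
        self.alpha = alpha
        self.families = list(families or _FAMILY_BLOCKS)
        unknown = set(self.families) - set(_FAMILY_BLOCKS)
        if unknown:
            raise ValueError(f"unknown families {sorted(unknown)}")

    def fit(self) -> "TuningResults":
        present = set(self.dataset.trials["context"])
        stats_long = []
        for fam in self.families:
            for blk in _FAMILY_BLOCKS[fam]:
                if blk not in present:
                    continue
                df = family_stats(self.dataset, fam, blk)
                df.insert(1, "family", fam)
                stats_long.append(df)
        stats_df = pd.concat(stats_long, ignore_index=True)
        return TuningResults(self, stats_df)


class TuningResults:
    """Per-neuron statistics, labels and context types.

    ``stats`` is long format (neuron_id, family, block, r, p, n);
    ``per_neuron`` is one wide row per neuron with a
    ``<family>_label_<block>`` sign label per block and a
    ``<family>_context`` type per family.
    """

    def __init__(self, model: NeuronTuningModel, stats_df: pd.DataFrame):
        self.model = model
        self.alpha = model.alpha
        self.stats = stats_df
        self.per_neuron = self._build_per_neuron()

    def _stat(self, neuron_id: str, family: str, block: str) -> CorrelationStat:
        m = self.stats
        row = m[(m.neuron_id == neuron_id) & (m.family == family)
                & (m.block == block)]
        if row.empty:
            return CorrelationStat(np.nan, np.nan, 0, block)
        row = row.iloc[0]
        return CorrelationStat(row["r"], row["p"], int(row["n"]), block)

    def _build_per_neuron(self) -> pd.DataFrame:
        wide: Dict[str, dict] = {n: {"neuron_id": n}
                                 for n in self.model.dataset.neuron_ids}
        for row in self.stats.itertuples():
            d = wide[row.neuron_id]
            d[f"{row.family}_r_{row.block}"] = row.r
            d[f"{row.family}_p_{row.block}"] = row.p
            d[f"{row.family}_label_{row.block}"] = sign_label(
                row.family, row.r, row.p, self.alpha)
        present = set(self.stats["block"])
        for fam in self.model.families:
            a, b, labels = _CONTEXT_PAIR[fam]
            for n, d in wide.items():
                if a in present and b in present:
                    d[f"{fam}_context"] = assign_context_type(
                        self._make_stat(d, fam, a), self._make_stat(d, fam, b),
                        self.alpha, labels)
                else:
                    d[f"{fam}_context"] = "none"
        return pd.DataFrame(list(wide.values()))

    @staticmethod
    def _make_stat(d: dict, fam: str, blk: str) -> CorrelationStat:
        return CorrelationStat(d.get(f"{fam}_r_{blk}", np.nan),
                               d.get(f"{fam}_p_{blk}", np.nan), 0, blk)

    # -- summaries ---------------------------------------------------------

    def counts(self, family: str) -> dict:
        """Taxonomy tabulation for one family: per-block labelled counts,
        sign split, and context-type counts."""
        a, b, labels = _CONTEXT_PAIR[family]
        pn = self.per_neuron
        out: dict = {"family": family, "n_neurons": len(pn)}
        for blk in (a, b):
            col = f"{family}_label_{blk}"
            if col not in pn:
                continue
            lab = pn[col]
            out[f"labelled_{blk}"] = int((lab != "none").sum())
            for s in set(_SIGN_LABELS[family]):
                out[f"{s}_{blk}"] = int((lab == s).sum())
        ctx = pn[f"{family}_context"]
        for c in list(labels) + ["sign_inconsistent"]:
            out[c] = int((ctx == c).sum())
        return out

    def summary(self) -> str:
        lines = [f"Neuron tuning classification (alpha={self.alpha}, "
                 f"n={len(self.per_neuron)} neurons)"]
        for fam in self.model.families:
            c = self.counts(fam)
            a, b, labels = _CONTEXT_PAIR[fam]
            lines.append(
                f"  {fam}: {c.get(f'labelled_{a}', 0)} labelled in {a}, "
                f"{c.get(f'labelled_{b}', 0)} in {b}; "
                + ", ".join(f"{c[l]} {l}" for l in labels)
                + f", {c['sign_inconsistent']} sign-inconsistent")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.per_neuron.copy()

    # -- group AUC profiles ------------------------------------------------

    def group_auc_profile(self, neuron_ids: Iterable[str],
                          window: str = "cs_test",
                          blocks: Sequence[str] = ("appetitive", "bivalent"),
                          conditions: Sequence[float] = (1.0, 0.5, 0.0),
                          ) -> pd.DataFrame:
        return group_auc_profile(self.model.dataset, list(neuron_ids),
                                 window=window, blocks=blocks,
                                 conditions=conditions)


def group_auc_profile(dataset: Dataset, neuron_ids: List[str],
                      window: str = "cs_test",
                      blocks: Sequence[str] = ("appetitive", "bivalent"),
                      conditions: Sequence[float] = (1.0, 0.5, 0.0),
                      ) -> pd.DataFrame:
    """Per-condition AUC profile of a neuron group.

    For each block and CS probability, each neuron's discrimination of the
    test window from its own pre-TC baseline is indexed by ROC-AUC; the
    group is tested per condition against 0.5 (Wilcoxon signed-rank,
    Bonferroni over the three conditions) and across conditions for a
    monotone trend (Spearman on pooled per-neuron AUCs).  Groups of one
    neuron get descriptive rows with the tests skipped.
    """
    if not neuron_ids:
        raise ValueError("empty neuron group")
    singleton = len(neuron_ids) < 2
    base_win = get_window("z_baseline")
    rows = []
    for blk in blocks:
        aucs_by_cond = {}
        for p in conditions:
            filt = (f"context == '{blk}' and kind == 'cued' "
                    f"and cs_probability == {p}")
            test = build_rate_table(dataset, window, filt)
            base = build_rate_table(dataset, base_win, filt)
            idx = [test.neuron_ids.index(n) for n in neuron_ids]
            aucs = np.array([roc_auc_index(test.rates[i], base.rates[i])
                             for i in idx])
            aucs_by_cond[p] = aucs
            if singleton:
                w_p = np.nan
            else:
                d = aucs - 0.5
                if np.allclose(d, 0):
                    w_p = 1.0
                else:
                    w_p = stats.wilcoxon(d).pvalue
            rows.append({"block": blk, "condition": p, "n": len(aucs),
                         "auc_mean": aucs.mean(),
                         "auc_sem": (aucs.std(ddof=1) / np.sqrt(len(aucs))
                                     if len(aucs) > 1 else np.nan),
                         "wilcoxon_p": w_p,
                         "significant": (not singleton) and
                         w_p < DEFAULT_ALPHA / len(conditions)})
        if singleton:
            rho, trend_p = np.nan, np.nan
        else:
            xs = np.concatenate([[p] * len(a) for p, a in aucs_by_cond.items()])
            ys = np.concatenate(list(aucs_by_cond.values()))
            rho, trend_p = stats.spearmanr(xs, ys)
        for r in rows:
            if r["block"] == blk and "trend_rho" not in r:
                r["trend_rho"] = rho
                r["trend_p"] = trend_p
    return pd.DataFrame(rows)
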