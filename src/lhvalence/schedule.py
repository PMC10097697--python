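"""Session schedule generation.

A session is three blocks: appetitive and aversive in seeded random order,
then the bivalent block last (the single-valence blocks provide the value
reference for the bivalent one).  Within a block the fixed trial multiset
(20 cued trials per CS, 10 per uncued type by default) is presented in a
seeded uniform permutation.  Outcomes are drawn from the context's
CS/outcome matrix:

==========  ==============  ==========================
context     cued p          delivered
==========  ==============  ==========================
appetitive  1.0 / 0.5 / 0   reward w.p. p, else tone
aversive    1.0 / 0.5 / 0   airpuff w.p. p, else tone
bivalent    1.0 / 0.5 / 0   reward w.p. p, else airpuff
==========  ==============  ==========================

Uncued (free) trials show the TC but no CS; their outcome is delivered at
the time it would occur in a cued trial, which makes it unpredictable.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import (
    CS_PROBABILITIES,
    TaskConfig,
    UNCUED_OUTCOME,
    UNCUED_TYPES,
    ConfigurationError,
)

TRIAL_COLUMNS = [
    "trial_id", "session_id", "block_index", "context", "kind",
    "cs_probability", "uncued_type", "tc_onset", "cs_onset", "trace_onset",
    "outcome_time", "trial_end", "delivered_outcome", "iti_ms",
]


def _draw_outcome(context: str, p: float, rng: np.random.Generator) -> str:
    hit = rng.random() < p
    if context == "appetitive":
        return "reward" if hit else "tone"
    if context == "aversive":
        return "airpuff" if hit else "tone"
    if context == "bivalent":
        return "reward" if hit else "airpuff"
    raise ConfigurationError(f"unknown context {context!r}")


def build_block(config: TaskConfig, context: str, block_index: int,
                rng: np.random.Generator, session_id: str = "s000",
                trial_offset: int = 0) -> pd.DataFrame:
    """Build one 80-trial block as a trial table."""
    if context not in UNCUED_TYPES:
        raise ConfigurationError(f"unknown context {context!r}")
    slots: list = []
    for p in CS_PROBABILITIES:
        slots += [("cued", p, None)] * config.trials_per_cs
    for ut in UNCUED_TYPES[context]:
        slots += [("uncued", None, ut)] * config.trials_per_uncued_type
    order = rng.permutation(len(slots))

    rows = []
    for i, k in enumerate(order):
        kind, p, uncued_type = slots[k]
        if kind == "cued":
            delivered = _draw_outcome(context, p, rng)
            cs_onset: Optional[int] = config.cs_onset
            trace_onset: Optional[int] = config.trace_onset
        else:
            delivered = UNCUED_OUTCOME[uncued_type]
            cs_onset = trace_onset = None
        iti = int(rng.integers(config.iti_range[0], config.iti_range[1] + 1))
        n = trial_offset + i
        rows.append({
            "trial_id": f"{session_id}_t{n:04d}",
            "session_id": session_id,
            "block_index": block_index,
            "context": context,
            "kind": kind,
            "cs_probability": p,
            "uncued_type": uncued_type,
            "tc_onset": config.tc_onset,
            "cs_onset": cs_onset,
            "trace_onset": trace_onset,
            # free outcomes fall at the cued outcome time so that the
            # pre-outcome trace epoch is defined on every trial
            "outcome_time": config.outcome_time,
            "trial_end": config.trial_end,
            "delivered_outcome": delivered,
            "iti_ms": iti,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def build_session_schedule(config: TaskConfig, seed: int,
                           session_id: str = "s000") -> pd.DataFrame:
    """Build the full three-block session trial table.

    Appetitive and aversive blocks come first in seeded random order; the
    bivalent block is always last.  The same (config, seed, session_id)
    always yields an identical table.
    """
    rng = np.random.default_rng(seed)
    first_two = ["appetitive", "aversive"]
    if rng.random() < 0.5:
        first_two.reverse()
    contexts = first_two + ["bivalent"]
    blocks = []
    offset = 0
    for bi, ctx in enumerate(contexts):
        blk = build_block(config, ctx, bi, rng, session_id=session_id,
                          trial_offset=offset)
        offset += len(blk)
        blocks.append(blk)
    out = pd.concat(blocks, ignore_index=True)
    out["cs_probability"] = out["cs_probability"].astype(float)
    return out
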