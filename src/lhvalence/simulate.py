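"""Synthetic neurons and behaviour with known ground-truth tuning.

Spike trains are drawn from an inhomogeneous Poisson process whose
intensity is a per-context baseline plus rectangular response kernels.
Each archetype family drives the kernel amplitude with one task variable:

``cs_value_pos`` / ``cs_value_neg``
    post-CS kernel scaling with reward probability (or its complement).
``pred_reward_pref`` / ``unpred_reward_pref``
    post-outcome kernel on delivered-reward trials scaling with how
    predictable delivery was (cued 100% = 1, cued 50% = 0.5, free = 0),
    or with its complement.
``uncertainty_50_highest`` / ``uncertainty_50_lowest``
    a trace-long bump (or dip) on 50% trials only.
``punishment_value``
    post-CS kernel scaling with airpuff probability.
``context_baseline_shift``
    whole-trial rate shift in the gated contexts.
``nonselective``
    baseline only (the null archetype).

A context gate multiplies the kernel gain by 1 in gated contexts and 0
elsewhere.  Intended intensities below zero are clamped to zero (counted,
never raised).  Because the intensity is piecewise constant, spikes are
generated exactly: per-segment Poisson counts with uniform times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    ConfigurationError,
    TaskConfig,
    airpuff_probability,
    reward_probability,
)
from .dataset import Dataset, NeuronRecording

log = logging.getLogger(__name__)

FAMILIES = (
    "cs_value_pos", "cs_value_neg",
    "unpred_reward_pref", "pred_reward_pref",
    "uncertainty_50_highest", "uncertainty_50_lowest",
    "punishment_value", "context_baseline_shift", "nonselective",
)

GATE_CONTEXTS = {
    "appetitive_only": ("appetitive",),
    "bivalent_only": ("bivalent",),
    "shared": ("appetitive", "bivalent"),
    "aversive_only": ("aversive",),
    "aversive_bivalent": ("aversive", "bivalent"),
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Ground-truth tuning of a synthetic neuron class.

    ``gain`` is in Hz per unit of the family's driving variable; the
    defaults (5 Hz baseline, 12 Hz gain) are typical of robustly modulated
    lateral-hypothalamus neurons.
    """

    family: str
    context_gate: str = "shared"
    baseline_rate: float = 5.0
    gain: float = 12.0
    kernel_onset: int = 100
    kernel_duration: int = 400
    blink_attenuation: float = 0.6   # behaviour model only; unused for spikes

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.context_gate not in GATE_CONTEXTS:
            raise ConfigurationError(
                f"unknown context_gate {self.context_gate!r}")
        if self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate must be >= 0")
        if not (0 < self.blink_attenuation <= 1):
            raise ConfigurationError("blink_attenuation must be in (0, 1]")


def _predictability_level(row) -> float:
    """How predictable the delivered US was: cued 100% -> 1, 50% -> 0.5,
    free -> 0, on the probability scale of the delivered outcome."""
    if row.kind == "uncued":
        return 0.0
    p = float(row.cs_probability)
    if row.delivered_outcome == "reward":
        return reward_probability(row.context, p)
    if row.delivered_outcome == "airpuff":
        return airpuff_probability(row.context, p)
    return 0.0


def _trial_segments(spec: ArchetypeSpec, row, cfg: TaskConfig,
                    clamp_counter: List[int]) -> Tuple[list, list, list]:
    """Piecewise-constant intensity for one trial: (starts, ends, rates)."""
    gated = row.context in GATE_CONTEXTS[spec.context_gate]
    base = spec.baseline_rate
    if spec.family == "context_baseline_shift" and gated:
        base = base + spec.gain

    delta = 0.0
    lo = hi = None
    if gated and spec.family != "context_baseline_shift":
        fam = spec.family
        if fam in ("cs_value_pos", "cs_value_neg") and row.kind == "cued":
            p = reward_probability(row.context, float(row.cs_probability))
            if row.context == "aversive":
                p = 0.0  # reward-value families are silent to airpuff CSs
                drive = 0.0
            else:
                drive = p if fam == "cs_value_pos" else 1.0 - p
            lo = row.cs_onset + spec.kernel_onset
            hi = lo + spec.kernel_duration
            delta = spec.gain * drive
        elif fam == "punishment_value" and row.kind == "cued":
            drive = airpuff_probability(row.context, float(row.cs_probability))
            lo = row.cs_onset + spec.kernel_onset
            hi = lo + spec.kernel_duration
            delta = spec.gain * drive
        elif fam in ("unpred_reward_pref", "pred_reward_pref"):
            if row.delivered_outcome == "reward":
                lvl = _predictability_level(row)
                drive = (1.0 - lvl) if fam == "unpred_reward_pref" else lvl
                lo = row.outcome_time + spec.kernel_onset
                hi = lo + spec.kernel_duration
                delta = spec.gain * drive
        elif fam in ("uncertainty_50_highest", "uncertainty_50_lowest"):
            if row.kind == "cued" and float(row.cs_probability) == 0.5:
                lo = row.trace_onset       # trace-long kernel
                hi = row.outcome_time
                delta = spec.gain if fam == "uncertainty_50_highest" else -spec.gain

    starts, ends, rates = [0.0], [], [base]
    if lo is not None and delta != 0.0 and lo < row.trial_end:
        lo = float(max(lo, 0))
        hi = float(min(hi, row.trial_end))
        r = base + delta
        if r < 0:
            clamp_counter[0] += 1
            r = 0.0
        starts = [0.0, lo, hi]
        ends = [lo, hi, float(row.trial_end)]
        rates = [base, r, base]
    else:
        ends = [float(row.trial_end)]
    return starts, ends, rates


def simulate_neuron_population(
    schedule: pd.DataFrame,
    archetypes: Sequence[ArchetypeSpec],
    n_per_archetype,
    seed: int,
    config: Optional[TaskConfig] = None,
    id_prefix: str = "n",
) -> Tuple[Dict[str, NeuronRecording], pd.DataFrame]:
    """Simulate neurons for every archetype; returns recordings + labels.

    ``n_per_archetype`` is an int (same count for all) or a sequence of
    counts aligned with ``archetypes``.  Every synthetic neuron receives a
    ground-truth label row.
    """
    cfg = config or TaskConfig()
    rng = np.random.default_rng(seed)
    if isinstance(n_per_archetype, int):
        counts = [n_per_archetype] * len(archetypes)
    else:
        counts = list(n_per_archetype)
        if len(counts) != len(archetypes):
            raise ConfigurationError(
                "n_per_archetype must match number of archetypes")

    trial_ids = list(schedule["trial_id"])
    n_trials = len(trial_ids)
    neurons: Dict[str, NeuronRecording] = {}
    labels = []
    k = 0
    for spec, n in zip(archetypes, counts):
        clamp = [0]
        # intensity segments are identical for all neurons of an archetype
        seg_start, seg_end, seg_rate, seg_trial = [], [], [], []
        for ti, row in enumerate(schedule.itertuples()):
            s, e, r = _trial_segments(spec, row, cfg, clamp)
            seg_start += s
            seg_end += e
            seg_rate += r
            seg_trial += [ti] * len(s)
        seg_start = np.asarray(seg_start)
        seg_dur = np.asarray(seg_end) - seg_start
        lam = np.asarray(seg_rate) * seg_dur / 1000.0
        seg_trial = np.asarray(seg_trial)
        if clamp[0]:
            log.warning("archetype %s/%s: intensity clamped to 0 in %d "
                        "trial segment(s)", spec.family, spec.context_gate,
                        clamp[0])

        for _ in range(n):
            c = rng.poisson(lam)
            rep = np.repeat(np.arange(lam.size), c)
            times = seg_start[rep] + rng.random(rep.size) * seg_dur[rep]
            tri = seg_trial[rep]
            order = np.lexsort((times, tri))
            times = np.floor(times[order]).astype(np.int32)
            tri = tri[order]
            offsets = np.zeros(n_trials + 1, dtype=np.int64)
            np.cumsum(np.bincount(tri, minlength=n_trials), out=offsets[1:])
            nid = f"{id_prefix}{k:05d}"
            neurons[nid] = NeuronRecording(nid, trial_ids, times, offsets,
                                           label=spec.family)
            labels.append({"neuron_id": nid, "family": spec.family,
                           "context_gate": spec.context_gate,
                           "gain": spec.gain,
                           "baseline_rate": spec.baseline_rate})
            k += 1
    return neurons, pd.DataFrame(labels)


@dataclass(frozen=True)
class BehaviorParams:
    """Targets of the anticipatory lick/blink generator (events ~ Poisson).

    During the anticipatory epoch (2 s before outcome, i.e. CS + trace) the
    lick rate is ``lick_base + lick_gain * P(reward)`` and the blink rate
    ``blink_base + blink_gain * P(airpuff)``; in the bivalent context blink
    rates are multiplied by the attenuation factor ``kappa`` (< 1 emulates
    the weaker avoidance when reward is also possible).  Outside that epoch
    both behaviours run at a low background rate.
    """

    lick_base: float = 1.0
    lick_gain: float = 6.0
    blink_base: float = 0.5
    blink_gain: float = 4.0
    kappa: float = 0.6
    background_rate: float = 0.2
    anticipatory_ms: int = 2000

    def __post_init__(self) -> None:
        if not (0 < self.kappa <= 1):
            raise ConfigurationError("kappa must be in (0, 1]")
        for name in ("lick_base", "lick_gain", "blink_base", "blink_gain",
                     "background_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def behavior_target_rates(params: BehaviorParams, context: str, kind: str,
                          cs_probability: float) -> Tuple[float, float]:
    """Anticipatory-epoch (lick, blink) target rates in Hz for a trial."""
    if kind == "cued":
        p_rew = reward_probability(context, float(cs_probability))
        p_air = airpuff_probability(context, float(cs_probability))
    else:
        p_rew = p_air = 0.0
    lick = params.lick_base + params.lick_gain * p_rew
    blink = params.blink_base + params.blink_gain * p_air
    if context == "bivalent":
        blink *= params.kappa
    return lick, blink


def simulate_behavior(schedule: pd.DataFrame, params: BehaviorParams,
                      seed: int) -> pd.DataFrame:
    """Per-trial lick and blink event times (long format)."""
    rng = np.random.default_rng(seed)
    rows = []
    for row in schedule.itertuples():
        t1 = float(row.outcome_time)
        t0 = t1 - params.anticipatory_ms
        for event, target in zip(
                ("lick", "blink"),
                behavior_target_rates(params, row.context, row.kind,
                                      row.cs_probability)):
            for (a, b, rate) in ((0.0, t0, params.background_rate),
                                 (t0, t1, target),
                                 (t1, float(row.trial_end),
                                  params.background_rate)):
                n = rng.poisson(rate * (b - a) / 1000.0)
                for t in np.sort(a + rng.random(n) * (b - a)):
                    rows.append((row.trial_id, event, int(t)))
    return pd.DataFrame(rows, columns=["trial_id", "event", "t_ms"])


def default_archetype_mix() -> List[Tuple[ArchetypeSpec, int]]:
    """A 240-neuron mix qualitatively mirroring the observed taxonomy:
    every response family in shared and context-dependent variants, a
    smaller punishment contingent, context baseline shifts of both signs,
    and a large untuned remainder."""
    mix: List[Tuple[ArchetypeSpec, int]] = []
    for fam in ("cs_value_pos", "cs_value_neg"):
        mix += [(ArchetypeSpec(fam, "shared"), 9),
                (ArchetypeSpec(fam, "appetitive_only"), 13),
                (ArchetypeSpec(fam, "bivalent_only"), 7)]
    for fam in ("unpred_reward_pref", "pred_reward_pref"):
        mix += [(ArchetypeSpec(fam, "shared"), 9),
                (ArchetypeSpec(fam, "appetitive_only"), 12),
                (ArchetypeSpec(fam, "bivalent_only"), 8)]
    for fam in ("uncertainty_50_highest", "uncertainty_50_lowest"):
        mix += [(ArchetypeSpec(fam, "shared"), 6),
                (ArchetypeSpec(fam, "appetitive_only"), 9),
                (ArchetypeSpec(fam, "bivalent_only"), 7)]
    mix += [(ArchetypeSpec("punishment_value", "aversive_only"), 7),
            (ArchetypeSpec("punishment_value", "aversive_bivalent"), 7)]
    mix += [(ArchetypeSpec("context_baseline_shift", "appetitive_only",
                           gain=5.0), 10),
            (ArchetypeSpec("context_baseline_shift", "aversive_only",
                           gain=-3.0), 10)]
    used = sum(n for _, n in mix)
    mix.append((ArchetypeSpec("nonselective"), 240 - used))
    return mix


def simulate_dataset(seed: int, config: Optional[TaskConfig] = None,
                     mix: Optional[Sequence[Tuple[ArchetypeSpec, int]]] = None,
                     behavior_params: Optional[BehaviorParams] = None,
                     session_id: str = "s000") -> Dataset:
    """One full synthetic session: schedule + spikes + behaviour + labels."""
    from .schedule import build_session_schedule

    cfg = config or TaskConfig()
    mix = list(mix) if mix is not None else default_archetype_mix()
    bp = behavior_params or BehaviorParams()
    ss = np.random.SeedSequence(seed)
    s_sched, s_spk, s_beh = [int(s.generate_state(1)[0] % (2**31))
                             for s in ss.spawn(3)]
    trials = build_session_schedule(cfg, s_sched, session_id=session_id)
    neurons, labels = simulate_neuron_population(
        trials, [a for a, _ in mix], [n for _, n in mix], s_spk, config=cfg,
        id_prefix=f"{session_id}_n")
    behavior = simulate_behavior(trials, bp, s_beh)
    manifest = {"seed": seed, "behavior_params": asdict(bp)}
    return Dataset(trials=trials, neurons=neurons, behavior=behavior,
                   labels=labels, config=cfg, manifest=manifest)
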