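"""In-memory dataset container and plain-text persistence.

A dataset is a trial table, per-neuron spike timestamp lists, optional
behaviour events (licks and blinks as point events) and optional
ground-truth tuning labels for synthetic neurons.  On disk it is a
directory of TSV tables plus a JSON manifest:

* ``trials.tsv``   — one row per trial (see ``schedule.TRIAL_COLUMNS``)
* ``spikes.tsv``   — long format ``neuron_id, trial_id, t_ms``
* ``behavior.tsv`` — long format ``trial_id, event, t_ms`` (event in
  ``lick``/``blink``); may be empty
* ``labels.tsv``   — ``neuron_id, family, context_gate, gain`` (synthetic
  data only)
* ``manifest.json`` — format version, task config, seeds

Timestamps are integer milliseconds from trial start (spikes are sampled
at 1 kHz in the emulated recordings); all windows downstream are half-open
in ms, so binning is exact and tie-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import TaskConfig, UNCUED_OUTCOME

FORMAT_VERSION = 1


class DatasetValidationError(ValueError):
    pass


class NeuronRecording:
    """Spike timestamps of one neuron across the trials of a session.

    Stored as a single flat int32 array with per-trial offsets (CSR-like),
    which keeps a session of a few hundred trials cheap and allows window
    counts across all trials in one vectorised call.
    """

    def __init__(self, neuron_id: str, trial_ids: Sequence[str],
                 flat: np.ndarray, offsets: np.ndarray,
                 subject_id: str = "sim", label: Optional[str] = None):
        self.neuron_id = neuron_id
        self.subject_id = subject_id
        self.trial_ids = list(trial_ids)
        self.label = label
        self.flat = np.asarray(flat, dtype=np.int32)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        if len(self.offsets) != len(self.trial_ids) + 1:
            raise DatasetValidationError(
                f"neuron {neuron_id}: offsets/trials length mismatch")
        self._index = {t: i for i, t in enumerate(self.trial_ids)}
        self._shifted: Optional[np.ndarray] = None
        self._span: int = 0

    @classmethod
    def from_trial_lists(cls, neuron_id: str, trial_ids: Sequence[str],
                         spike_lists: Sequence[Iterable[float]],
                         **kw) -> "NeuronRecording":
        arrays = [np.asarray(sorted(s), dtype=np.int32) for s in spike_lists]
        offsets = np.concatenate([[0], np.cumsum([len(a) for a in arrays])])
        flat = (np.concatenate(arrays) if arrays
                else np.empty(0, dtype=np.int32))
        return cls(neuron_id, trial_ids, flat, offsets, **kw)

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    @property
    def n_spikes(self) -> int:
        return int(self.offsets[-1])

    def spikes_for(self, trial_id: str) -> np.ndarray:
        i = self._index[trial_id]
        return self.flat[self.offsets[i]:self.offsets[i + 1]]

    def _shifted_times(self):
        # each trial's spikes shifted into a disjoint band, so one global
        # searchsorted resolves any set of per-trial windows at once
        if self._shifted is None:
            self._span = int(self.flat.max(initial=0)) + 1
            bands = np.repeat(
                np.arange(self.n_trials, dtype=np.int64) * self._span,
                np.diff(self.offsets))
            self._shifted = self.flat.astype(np.int64) + bands
        return self._shifted, self._span

    def window_counts(self, trial_index: np.ndarray, starts: np.ndarray,
                      ends: np.ndarray) -> np.ndarray:
        """Spike counts in half-open windows ``[start, end)`` per trial.

        ``trial_index`` selects trials by position in ``self.trial_ids``;
        ``starts``/``ends`` are absolute ms within each trial.  The three
        arguments broadcast, so a (n_windows, 1) offset grid against a
        (n_trials,) trial index yields a full window x trial count matrix.
        """
        trial_index = np.asarray(trial_index, dtype=np.int64)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        lo = self.offsets[trial_index]
        hi = self.offsets[trial_index + 1]
        shifted, span = self._shifted_times()
        a = np.searchsorted(shifted, trial_index * span + starts, side="left")
        b = np.searchsorted(shifted, trial_index * span + ends, side="left")
        # clip to the trial's own slice (windows never cross trials)
        return (np.minimum(b, hi) - np.maximum(a, lo)).clip(min=0)

    def validate(self, trial_end: Dict[str, int]) -> None:
        for i, t in enumerate(self.trial_ids):
            s = self.flat[self.offsets[i]:self.offsets[i + 1]]
            if s.size == 0:
                continue
            if np.any(np.diff(s) < 0):
                raise DatasetValidationError(
                    f"neuron {self.neuron_id}, trial {t}: spikes not sorted")
            if s[0] < 0 or s[-1] >= trial_end[t]:
                raise DatasetValidationError(
                    f"neuron {self.neuron_id}, trial {t}: spike outside "
                    f"[0, {trial_end[t]})")


@dataclass
class Dataset:
    """A session (or multi-session) dataset ready for analysis."""

    trials: pd.DataFrame
    neurons: Dict[str, NeuronRecording] = field(default_factory=dict)
    behavior: Optional[pd.DataFrame] = None
    labels: Optional[pd.DataFrame] = None
    config: TaskConfig = field(default_factory=TaskConfig)
    manifest: dict = field(default_factory=dict)

    @property
    def neuron_ids(self) -> List[str]:
        return list(self.neurons)

    def validate(self) -> None:
        _validate_trials(self.trials)
        trial_end = dict(zip(self.trials["trial_id"],
                             self.trials["trial_end"].astype(int)))
        known = set(trial_end)
        for nr in self.neurons.values():
            missing = [t for t in nr.trial_ids if t not in known]
            if missing:
                raise DatasetValidationError(
                    f"neuron {nr.neuron_id} references unknown trial(s) "
                    f"{missing[:3]}")
            nr.validate(trial_end)
        if self.behavior is not None and len(self.behavior):
            bad = set(self.behavior["trial_id"]) - known
            if bad:
                raise DatasetValidationError(
                    f"behavior references unknown trial(s) {sorted(bad)[:3]}")


def _allowed_outcomes(context: str, p: float) -> set:
    """Outcomes consistent with the context's CS/outcome matrix."""
    us = {"appetitive": "reward", "aversive": "airpuff",
          "bivalent": "reward"}[context]
    alt = "airpuff" if context == "bivalent" else "tone"
    if p == 1.0:
        return {us}
    if p == 0.0:
        return {alt}
    return {us, alt}


def _validate_trials(trials: pd.DataFrame) -> None:
    for row in trials.itertuples():
        cued = row.kind == "cued"
        has_p = not pd.isna(row.cs_probability)
        has_u = isinstance(row.uncued_type, str)
        if cued != has_p or cued == has_u:
            raise DatasetValidationError(
                f"trial {row.trial_id}: exactly one of cs_probability / "
                "uncued_type must be present")
        if cued:
            allowed = _allowed_outcomes(row.context, float(row.cs_probability))
            if row.delivered_outcome not in allowed:
                raise DatasetValidationError(
                    f"trial {row.trial_id}: outcome {row.delivered_outcome!r} "
                    f"inconsistent with {row.context} p={row.cs_probability}")
        else:
            if UNCUED_OUTCOME[row.uncued_type] != row.delivered_outcome:
                raise DatasetValidationError(
                    f"trial {row.trial_id}: uncued outcome mismatch")


def write_dataset(dataset: Dataset, path) -> dict:
    """Write the dataset as TSV tables + manifest; returns the manifest."""
    dataset.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.trials.to_csv(path / "trials.tsv", sep="\t", index=False)

    with open(path / "spikes.tsv", "w") as fh:
        fh.write("neuron_id\ttrial_id\tt_ms\n")
        for nr in dataset.neurons.values():
            for i, tid in enumerate(nr.trial_ids):
                for t in nr.flat[nr.offsets[i]:nr.offsets[i + 1]]:
                    fh.write(f"{nr.neuron_id}\t{tid}\t{int(t)}\n")

    beh = dataset.behavior
    if beh is None:
        beh = pd.DataFrame(columns=["trial_id", "event", "t_ms"])
    beh.to_csv(path / "behavior.tsv", sep="\t", index=False)

    if dataset.labels is not None:
        dataset.labels.to_csv(path / "labels.tsv", sep="\t", index=False)

    subjects = {nr.neuron_id: nr.subject_id for nr in dataset.neurons.values()}
    manifest = {
        "format_version": FORMAT_VERSION,
        "task_config": dataset.config.to_dict(),
        "subjects": subjects,
        **{k: v for k, v in dataset.manifest.items()
           if k not in ("format_version", "task_config", "subjects")},
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def read_dataset(path) -> Dataset:
    """Load and fully re-validate a dataset directory."""
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != FORMAT_VERSION:
        raise DatasetValidationError(
            f"unsupported format version {manifest.get('format_version')!r}")
    config = TaskConfig.from_dict(manifest["task_config"])

    trials = pd.read_csv(path / "trials.tsv", sep="\t",
                         dtype={"uncued_type": "object"})
    trials["uncued_type"] = trials["uncued_type"].where(
        trials["uncued_type"].notna(), None)

    try:
        spikes = pd.read_csv(path / "spikes.tsv", sep="\t")
    except pd.errors.ParserError as e:
        raise DatasetValidationError(f"spikes.tsv parse error: {e}") from e
    trial_order = {t: i for i, t in enumerate(trials["trial_id"])}
    neurons: Dict[str, NeuronRecording] = {}
    subjects = manifest.get("subjects", {})
    if len(spikes):
        for nid, grp in spikes.groupby("neuron_id", sort=True):
            lists: Dict[str, list] = {t: [] for t in trials["trial_id"]}
            for tid, t in zip(grp["trial_id"], grp["t_ms"]):
                if tid not in lists:
                    raise DatasetValidationError(
                        f"neuron {nid} references unknown trial {tid!r}")
                lists[tid].append(int(t))
            ordered = sorted(lists, key=trial_order.get)
            neurons[str(nid)] = NeuronRecording.from_trial_lists(
                str(nid), ordered, [lists[t] for t in ordered],
                subject_id=subjects.get(str(nid), "unknown"))

    beh_path = path / "behavior.tsv"
    behavior = pd.read_csv(beh_path, sep="\t") if beh_path.exists() else None
    if behavior is not None and behavior.empty:
        behavior = behavior  # kept: downstream reports "not available"

    lab_path = path / "labels.tsv"
    labels = pd.read_csv(lab_path, sep="\t") if lab_path.exists() else None

    ds = Dataset(trials=trials, neurons=neurons, behavior=behavior,
                 labels=labels, config=config, manifest=manifest)
    ds.validate()
    return ds
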