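"""Windowed rates, z-scored PSTHs and the ROC-AUC discrimination index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lhvalence import (
    WindowDef,
    build_rate_table,
    count_rate,
    n_sliding_windows,
    roc_auc_index,
    simulate_dataset,
    zscore_psth,
)
from lhvalence.simulate import ArchetypeSpec

from conftest import dataset_from_neurons, make_deterministic_neuron


class TestCountRate:
    def test_arithmetic(self):
        # three spikes in the 199-ms test window -> 3 / 0.2 s
        assert count_rate([250, 300, 350], 201, 401) == pytest.approx(15.0)

    def test_empty(self):
        assert count_rate([], 201, 401) == 0.0

    def test_end_exclusive(self):
        assert count_rate([400], 201, 401) == pytest.approx(5.0)
        assert count_rate([401], 201, 401) == 0.0

    def test_window_outside_trial_errors(self):
        with pytest.raises(ValueError):
            count_rate([1], 100, 50)
        with pytest.raises(ValueError):
            count_rate([1], -10, 50)
        with pytest.raises(ValueError):
            count_rate([1], 0, 100, trial_end=50)


@pytest.fixture(scope="module")
def sim_dataset():
    from lhvalence import TaskConfig
    cfg = TaskConfig(trials_per_cs=4, trials_per_uncued_type=2)
    return simulate_dataset(19, config=cfg,
                            mix=[(ArchetypeSpec("nonselective"), 4)])


class TestRateTable:
    def test_row_counts(self, sim_dataset):
        rt = build_rate_table(sim_dataset, "cs_test", "kind == 'cued'")
        n_cued = (sim_dataset.trials.kind == "cued").sum()
        assert rt.rates.shape == (4, n_cued)

    def test_filter_semantics(self, sim_dataset):
        rt = build_rate_table(
            sim_dataset, "us_test",
            "context == 'appetitive' and delivered_outcome == 'reward'")
        assert (rt.trials["delivered_outcome"] == "reward").all()
        assert not (rt.trials["cs_probability"] == 0.0).any()

    def test_deterministic(self, sim_dataset):
        a = build_rate_table(sim_dataset, "cs_test", "kind == 'cued'")
        b = build_rate_table(sim_dataset, "cs_test", "kind == 'cued'")
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_empty_filter_errors(self, sim_dataset):
        with pytest.raises(ValueError, match="selects no trials"):
            build_rate_table(sim_dataset, "cs_test", "context == 'lunar'")

    def test_undefined_anchor_errors(self, sim_dataset):
        with pytest.raises(ValueError, match="undefined"):
            build_rate_table(sim_dataset, "cs_test", None)  # uncued included


class TestZScore:
    def test_degenerate_baseline_flagged(self, small_schedule, small_config):
        # exact 10 Hz baseline on every trial -> SD 0; bins that depart
        # from the baseline mean flag the neuron as degenerate
        nr = make_deterministic_neuron(small_schedule, "z_baseline",
                                       lambda row: 10.0)
        ds = dataset_from_neurons(small_schedule, [nr], small_config)
        psth = zscore_psth(ds, bin_ms=200, step_ms=50)
        for ctx, z in psth.z.items():
            # no spikes outside baseline: bins are 0 Hz != 10 Hz baseline
            assert psth.degenerate[ctx][0]

    def test_bin_count_closed_form(self, sim_dataset):
        psth = zscore_psth(sim_dataset, bin_ms=200, step_ms=50)
        # 2000-ms CS+trace span, 200-ms bins, 50-ms step -> 37 bins
        assert psth.z["appetitive"].shape[1] == 37 == n_sliding_windows(
            2000, 200, 50)

    def test_baseline_window_zscores_to_zero_mean(self, sim_dataset):
        from lhvalence import build_rate_table
        ds = sim_dataset
        for ctx in ("appetitive",):
            base = build_rate_table(
                ds, "z_baseline", f"context == '{ctx}' and kind == 'cued'")
            mu = base.rates.mean(axis=1)
            sd = base.rates.std(axis=1)
            z = (base.rates - mu[:, None]) / sd[:, None]
            np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)


def _auc_bruteforce(a, b):
    wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    return wins / (len(a) * len(b))


class TestAUC:
    @pytest.mark.parametrize("test,base,expected", [
        ([5, 5, 5], [5, 5, 5], 0.5),          # identical samples
        ([10, 12], [1, 2], 1.0),              # full separation
        ([2, 4, 6], [3, 5], 0.5),             # pair-count oracle: 3/6
    ])
    def test_examples(self, test, base, expected):
        assert roc_auc_index(test, base) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            roc_auc_index([], [1.0])

    @settings(deadline=None, max_examples=200)
    @given(st.data())
    def test_matches_bruteforce_oracle(self, data):
        a = data.draw(st.lists(st.integers(0, 8), min_size=1, max_size=8))
        b = data.draw(st.lists(st.integers(0, 8), min_size=1, max_size=8))
        assert roc_auc_index(a, b) == pytest.approx(_auc_bruteforce(a, b))

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_complement_identity(self, data):
        a = data.draw(st.lists(st.floats(0, 50, allow_nan=False),
                               min_size=1, max_size=10))
        b = data.draw(st.lists(st.floats(0, 50, allow_nan=False),
                               min_size=1, max_size=10))
        assert roc_auc_index(a, b) + roc_auc_index(b, a) == pytest.approx(1.0)


@settings(deadline=None, max_examples=100)
@given(span=st.integers(1, 5000), win=st.integers(1, 1000),
       step=st.integers(1, 500))
def test_sliding_window_count_closed_form(span, win, step):
    n = n_sliding_windows(span, win, step)
    # oracle: enumerate starts whose window fits inside the span
    starts = [s for s in range(0, span + 1, step) if s + win <= span]
    assert n == len(starts)
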