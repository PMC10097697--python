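"""Per-neuron tuning statistics, labels and context types."""

import numpy as np
import pandas as pd
import pytest

from lhvalence import (
    CorrelationStat,
    NeuronTuningModel,
    assign_context_type,
    cs_value_stat,
    group_auc_profile,
    predictability_stat,
    simulate_dataset,
    uncertainty_stat,
)
from lhvalence.simulate import ArchetypeSpec
from lhvalence.tuning import pearson_with_p, sign_label

from conftest import dataset_from_neurons, make_deterministic_neuron


def _stat(r, p):
    return CorrelationStat(r, p, 60, "x")


class TestContextType:
    """assign_context_type is a pure deterministic mapping."""

    def test_both_significant_same_sign(self):
        assert assign_context_type(_stat(0.5, 0.01), _stat(0.4, 0.01)) \
            == "appetitive_bivalent"

    def test_single_block(self):
        assert assign_context_type(_stat(0.5, 0.01), _stat(0.1, 0.5)) \
            == "appetitive_only"
        assert assign_context_type(_stat(0.1, 0.5), _stat(-0.5, 0.01)) \
            == "bivalent_only"

    def test_opposite_signs(self):
        assert assign_context_type(_stat(0.5, 0.01), _stat(-0.5, 0.01)) \
            == "sign_inconsistent"

    def test_none(self):
        assert assign_context_type(_stat(0.1, 0.6), _stat(0.1, 0.6)) == "none"
        assert assign_context_type(_stat(np.nan, np.nan),
                                   _stat(0.1, 0.6)) == "none"

    def test_punishment_labels(self):
        labels = ("aversive_only", "bivalent_only", "aversive_bivalent")
        assert assign_context_type(_stat(0.5, 0.01), _stat(0.4, 0.01),
                                   labels=labels) == "aversive_bivalent"


@pytest.fixture(scope="module")
def ds(small_schedule, small_config):
    # rates graded with reward probability in the CS test window
    def val(row):
        return {0.0: 5.0, 0.5: 10.0, 1.0: 15.0}[row.cs_probability] \
            if row.kind == "cued" else 0.0

    def val_neg(row):
        return {0.0: 15.0, 0.5: 10.0, 1.0: 5.0}[row.cs_probability] \
            if row.kind == "cued" else 0.0
    up = make_deterministic_neuron(small_schedule, "cs_test", val, "pos")
    dn = make_deterministic_neuron(small_schedule, "cs_test", val_neg, "neg")
    flat = make_deterministic_neuron(small_schedule, "cs_test",
                                     lambda r: 10.0, "flat")
    return dataset_from_neurons(small_schedule, [up, dn, flat], small_config)


class TestNoiselessExamples:
    """Exact-count neurons recover the textbook labels."""

    def test_positive_type(self, ds):
        st = cs_value_stat(ds, "pos", "appetitive")
        assert st.r == pytest.approx(1.0)
        assert sign_label("cs_value", st.r, st.p) == "positive"

    def test_negative_type(self, ds):
        st = cs_value_stat(ds, "neg", "appetitive")
        assert st.r == pytest.approx(-1.0)
        assert sign_label("cs_value", st.r, st.p) == "negative"

    def test_flat_is_none(self, ds):
        st = cs_value_stat(ds, "flat", "appetitive")
        assert sign_label("cs_value", st.r, st.p) == "none"


class TestPredictabilityExamples:
    def test_unpredicted_preferring_monotone(self, small_schedule,
                                             small_config):
        # 15 Hz free / 10 Hz at 50% / 5 Hz at 100% delivered rewards
        def rate(row):
            if row.delivered_outcome != "reward":
                return 0.0
            if row.kind == "uncued":
                return 15.0
            return {0.5: 10.0, 1.0: 5.0}.get(row.cs_probability, 0.0)
        nr = make_deterministic_neuron(small_schedule, "us_test", rate, "u")
        ds = dataset_from_neurons(small_schedule, [nr], small_config)
        st = predictability_stat(ds, "u", "appetitive")
        assert st.r < 0
        assert sign_label("predictability", st.r, st.p) == "unpredicted_pref"

    def test_missing_level_gives_none(self, small_schedule, small_config):
        # aversive block has no delivered rewards at all
        nr = make_deterministic_neuron(small_schedule, "us_test",
                                       lambda r: 5.0, "x")
        ds = dataset_from_neurons(small_schedule, [nr], small_config)
        st = predictability_stat(ds, "x", "aversive")
        assert not st.defined


class TestUncertaintyExamples:
    @pytest.mark.parametrize("rates,expected", [
        ({1.0: 10.0, 0.5: 20.0, 0.0: 10.0}, "highest_50"),
        ({1.0: 20.0, 0.5: 10.0, 0.0: 20.0}, "lowest_50"),
    ])
    def test_u_shapes(self, small_schedule, small_config, rates, expected):
        def rate(row):
            return rates[row.cs_probability] if row.kind == "cued" else 0.0
        nr = make_deterministic_neuron(small_schedule, "trace_uncertainty",
                                       rate, "u")
        ds = dataset_from_neurons(small_schedule, [nr], small_config)
        st = uncertainty_stat(ds, "u", "appetitive")
        assert sign_label("uncertainty", st.r, st.p) == expected


def test_pearson_vectorised_matches_scipy():
    from scipy.stats import pearsonr
    rng = np.random.default_rng(8)
    x = rng.normal(size=30)
    Y = rng.normal(size=(5, 30))
    r, p = pearson_with_p(x, Y)
    for i in range(5):
        ref = pearsonr(x, Y[i])
        assert r[i] == pytest.approx(ref.statistic)
        assert p[i] == pytest.approx(ref.pvalue, rel=1e-6)


def test_label_invariant_to_neuron_order():
    """Permuting neuron order never changes any per-neuron label."""
    from lhvalence import TaskConfig
    cfg = TaskConfig(trials_per_cs=10, trials_per_uncued_type=5)
    mix = [(ArchetypeSpec("cs_value_pos", "shared"), 3),
           (ArchetypeSpec("nonselective"), 3)]
    ds = simulate_dataset(5, config=cfg, mix=mix)
    res = NeuronTuningModel(ds).fit()
    ds2 = dataset_from_neurons(
        ds.trials, list(ds.neurons.values())[::-1], cfg)
    res2 = NeuronTuningModel(ds2).fit()
    a = res.per_neuron.set_index("neuron_id").sort_index()
    b = res2.per_neuron.set_index("neuron_id").sort_index()
    pd.testing.assert_frame_equal(a, b)


class TestGroupAUC:
    def test_positive_group_auc_increases_with_probability(self):
        from lhvalence import TaskConfig
        cfg = TaskConfig(trials_per_cs=20, trials_per_uncued_type=5)
        mix = [(ArchetypeSpec("cs_value_pos", "shared"), 8)]
        ds = simulate_dataset(9, config=cfg, mix=mix)
        prof = group_auc_profile(ds, ds.neuron_ids, blocks=("appetitive",))
        m = prof.set_index("condition")["auc_mean"]
        assert m[1.0] > m[0.5] > m[0.0]
        assert prof.set_index("condition")["significant"][1.0]
        assert prof["trend_rho"].iloc[0] > 0

    def test_full_separation_gives_auc_one(self, small_schedule,
                                            small_config):
        def rate(row):
            return 40.0 if (row.kind == "cued"
                            and row.cs_probability == 1.0) else 0.0
        group = [make_deterministic_neuron(small_schedule, "cs_test", rate,
                                           f"g{i}") for i in range(3)]
        ds = dataset_from_neurons(small_schedule, group, small_config)
        prof = group_auc_profile(ds, ds.neuron_ids, blocks=("appetitive",))
        assert prof.set_index("condition")["auc_mean"][1.0] \
            == pytest.approx(1.0)

    def test_singleton_group_skips_tests(self, small_schedule, small_config):
        nr = make_deterministic_neuron(small_schedule, "cs_test",
                                       lambda r: 5.0, "solo")
        ds = dataset_from_neurons(small_schedule, [nr], small_config)
        prof = group_auc_profile(ds, ["solo"], blocks=("appetitive",))
        assert prof["wilcoxon_p"].isna().all()
        assert not prof["significant"].any()

    def test_empty_group_errors(self, small_schedule, small_config):
        nr = make_deterministic_neuron(small_schedule, "cs_test",
                                       lambda r: 5.0, "a")
        ds = dataset_from_neurons(small_schedule, [nr], small_config)
        with pytest.raises(ValueError):
            group_auc_profile(ds, [])
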