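"""Population analyses: block PSTH comparison, sliding correlation, PCA,
context modulation."""

import numpy as np
import pandas as pd
import pytest

from lhvalence import (
    TaskConfig,
    context_modulation_stats,
    crossblock_sensitivity_series,
    pca_state_space,
    population_block_comparison,
    simulate_dataset,
)
from lhvalence.simulate import ArchetypeSpec

from conftest import dataset_from_neurons, make_deterministic_neuron


@pytest.fixture(scope="module")
def value_mix_dataset():
    cfg = TaskConfig(trials_per_cs=15, trials_per_uncued_type=5)
    mix = [(ArchetypeSpec("cs_value_pos", "shared", kernel_duration=1800), 12),
           (ArchetypeSpec("cs_value_neg", "shared", kernel_duration=1800), 12),
           (ArchetypeSpec("nonselective"), 12)]
    return simulate_dataset(31, config=cfg, mix=mix)


class TestBlockComparison:
    def test_aversive_trace_deficit_flagged(self):
        """A population whose late-trace drive exists only in appetitive and
        bivalent blocks shows aversive-lower flags in late-trace bins."""
        cfg = TaskConfig(trials_per_cs=12, trials_per_uncued_type=4)
        # uncertainty bump on 50% trials, gated out of the aversive block,
        # plus sustained CS drive shared by appetitive/bivalent
        mix = [(ArchetypeSpec("cs_value_pos", "shared",
                              kernel_duration=1800), 20),
               (ArchetypeSpec("nonselective"), 10)]
        ds = simulate_dataset(41, config=cfg, mix=mix)
        out = population_block_comparison(ds)
        late = out[out["bin_start"] >= 1400]
        flags = late["tukey_appetitive_vs_aversive"] & (
            late["diff_appetitive_vs_aversive"] < 0)
        assert flags.any()

    def test_identical_generators_calibrate_to_alpha(self):
        cfg = TaskConfig(trials_per_cs=8, trials_per_uncued_type=4)
        ds = simulate_dataset(43, config=cfg,
                              mix=[(ArchetypeSpec("nonselective"), 40)])
        out = population_block_comparison(ds)
        assert out["significant"].mean() < 0.25

    def test_single_bin_input(self, value_mix_dataset):
        out = population_block_comparison(value_mix_dataset, bin_ms=2000,
                                          step_ms=2000)
        assert len(out) == 1
        assert {"F", "p", "significant"} <= set(out.columns)


class TestSlidingSeries:
    def test_window_count_closed_form(self, value_mix_dataset):
        s = crossblock_sensitivity_series(value_mix_dataset,
                                          ("appetitive", "bivalent"),
                                          "cs_value", 200, 10)
        # 2000-ms CS+trace span, 200-ms window, 10-ms step -> 181 windows
        assert len(s.window_starts) == 181

    def test_shared_tuning_positive_rho(self, value_mix_dataset):
        s = crossblock_sensitivity_series(value_mix_dataset,
                                          ("appetitive", "bivalent"),
                                          "cs_value", 200, 10)
        core = (s.window_starts >= 100) & (s.window_starts <= 1700)
        assert (s.rho[core] > 0).mean() > 0.9
        assert s.significant[core].mean() > 0.9

    def test_unrelated_blocks_near_zero(self, value_mix_dataset):
        # appetitive vs aversive: the value archetypes are silent to
        # airpuff CSs, so cross-block sensitivity has no shared structure
        s = crossblock_sensitivity_series(value_mix_dataset,
                                          ("appetitive", "aversive"),
                                          "cs_value", 200, 10)
        assert abs(np.nanmedian(s.rho)) < 0.3

    def test_oversized_window_errors(self, value_mix_dataset):
        with pytest.raises(ValueError):
            crossblock_sensitivity_series(value_mix_dataset,
                                          ("appetitive", "bivalent"),
                                          "cs_value", win_ms=3000)


@pytest.fixture(scope="module")
def pca_result(value_mix_dataset):
    return pca_state_space(value_mix_dataset)


class TestPCA:

    def test_orthonormal_loadings(self, pca_result):
        G = pca_result.loadings @ pca_result.loadings.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_variance_non_increasing(self, pca_result):
        ev = pca_result.explained_variance_ratio
        assert np.all(np.diff(ev) <= 1e-12)

    def test_reconstruction_identity(self, value_mix_dataset, pca_result):
        """Projecting onto the full basis and back recovers the centred
        training matrix."""
        # rebuild the training matrix through the same path
        from lhvalence.rates import window_grid_rates
        cols = []
        for blk, p in pca_result.conditions:
            filt = (f"context == '{blk}' and kind == 'cued' "
                    f"and cs_probability == {p}")
            grid, _ = window_grid_rates(value_mix_dataset, "cs_onset",
                                        pca_result.bin_starts, 100, filt)
            cols.append(grid.mean(axis=2).T)
        X = np.concatenate(cols, axis=0)
        scores = pca_result.project(X)
        recon = scores @ pca_result.loadings + pca_result.mean_
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_training_vector_projects_to_trajectory_point(
            self, value_mix_dataset, pca_result):
        blk, p = pca_result.conditions[0]
        from lhvalence.rates import window_grid_rates
        filt = (f"context == '{blk}' and kind == 'cued' "
                f"and cs_probability == {p}")
        grid, _ = window_grid_rates(value_mix_dataset, "cs_onset",
                                    pca_result.bin_starts, 100, filt)
        vec = grid.mean(axis=2).T[0]       # first bin of that condition
        np.testing.assert_allclose(pca_result.project(vec)[0],
                                   pca_result.trajectories[(blk, p)][0],
                                   atol=1e-8)

    def test_block_offsets_separate_in_pc_space(self, small_schedule,
                                                small_config):
        """Constructed per-block additive offsets separate block centroids
        in the PC1-PC2 plane."""
        offsets = {"appetitive": 0.0, "aversive": 12.0, "bivalent": 24.0}
        neurons = []
        rng = np.random.default_rng(2)
        base = rng.uniform(3, 10, size=6)
        for i in range(6):
            def rate(row, i=i):
                return base[i] + offsets[row.context]
            neurons.append(make_deterministic_neuron(
                small_schedule, "cs_test", rate, f"p{i}"))
        ds = dataset_from_neurons(small_schedule, neurons, small_config)
        res = pca_state_space(ds, bin_ms=500)
        cent = {}
        for (blk, p), traj in res.trajectories.items():
            cent.setdefault(blk, []).append(traj[:, :2].mean(axis=0))
        cent = {b: np.mean(v, axis=0) for b, v in cent.items()}
        d_blocks = np.linalg.norm(cent["aversive"] - cent["appetitive"])
        assert d_blocks > 1.0


class TestContextModulation:
    def test_null_population_calibrates(self):
        cfg = TaskConfig(trials_per_cs=12, trials_per_uncued_type=4)
        ds = simulate_dataset(53, config=cfg,
                              mix=[(ArchetypeSpec("nonselective"), 150)])
        st = context_modulation_stats(ds, "context_baseline")
        assert st["per_cell_fraction"] < 0.12

    def test_sign_balanced_shifts_cellular_not_population(self):
        """Balanced up/down context shifts: many modulated cells but no
        population-level block difference."""
        cfg = TaskConfig(trials_per_cs=12, trials_per_uncued_type=4)
        mix = [(ArchetypeSpec("context_baseline_shift", "appetitive_only",
                              gain=4.0), 25),
               (ArchetypeSpec("context_baseline_shift", "appetitive_only",
                              gain=-4.0, baseline_rate=9.0), 25)]
        ds = simulate_dataset(59, config=cfg, mix=mix)
        st = context_modulation_stats(ds, "context_baseline")
        assert st["per_cell_fraction"] > 0.8
        assert st["population_p"] > 0.05

    def test_uniform_shift_detected_at_population_level(self):
        cfg = TaskConfig(trials_per_cs=12, trials_per_uncued_type=4)
        mix = [(ArchetypeSpec("context_baseline_shift", "appetitive_only",
                              gain=2.0), 40)]
        ds = simulate_dataset(61, config=cfg, mix=mix)
        st = context_modulation_stats(ds, "context_baseline")
        assert st["population_p"] < 0.05
        assert st["pairwise_counts"]["appetitive_vs_aversive"] > 10
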