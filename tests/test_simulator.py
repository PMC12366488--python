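import numpy as np
import pandas as pd
import pytest

from screpsim import DESpec, simulate_dataset, downsample_dataset
from screpsim.simulator import (
    draw_library_sizes,
    poisson_observe,
    resolve_de_spec,
    scaled_dirichlet_factors,
    simulate_sample_means,
    simulate_true_expression,
    symmetric_dirichlet_concentration,
)

from conftest import make_params


class TestScaledDirichletFactors:
    def test_degenerate_dimension(self):
        rng = np.random.default_rng(0)
        assert scaled_dirichlet_factors(1, 0.7, rng).tolist() == [[1.0]]

    def test_zero_variance(self):
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(
            scaled_dirichlet_factors(5, 0.0, rng), np.ones((1, 5))
        )

    def test_concentration_arithmetic(self):
        assert symmetric_dirichlet_concentration(5, 0.5) == pytest.approx(1.4)

    def test_component_variance(self):
        rng = np.random.default_rng(1)
        f = scaled_dirichlet_factors(5, 0.5, rng, size=30000)
        assert f.var(axis=0).mean() == pytest.approx(0.5, rel=0.05)

    def test_sum_exact(self):
        rng = np.random.default_rng(2)
        f = scaled_dirichlet_factors(7, 1.2, rng, size=100)
        np.testing.assert_allclose(f.sum(axis=1), 7.0, rtol=0, atol=1e-9)

    def test_variance_clamped(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="clamp"):
            f = scaled_dirichlet_factors(3, 5.0, rng)
        assert np.isfinite(f).all()

    def test_zero_dimension_errors(self):
        with pytest.raises(ValueError):
            scaled_dirichlet_factors(0, 0.5, np.random.default_rng(0))


class TestSimulateSampleMeans:
    def test_no_hierarchy_limit(self):
        params = make_params(mu_a=-25.0, sigma_a=0.0, mu_b=-25.0, sigma_b=0.0)
        mu, a, b = simulate_sample_means(params, np.random.default_rng(0))
        np.testing.assert_allclose(
            mu, np.repeat(params.gene_means[:, None], 8, axis=1)
        )
        assert (a == 1).all() and (b == 1).all()

    def test_conservation_identities(self, small_params):
        mu, a, b = simulate_sample_means(small_params, np.random.default_rng(1))
        m, n = small_params.n_subjects, small_params.n_timepoints
        np.testing.assert_allclose(a.sum(axis=1), m, atol=1e-9)
        np.testing.assert_allclose(b.sum(axis=2), n, atol=1e-9)

    def test_mean_factor_variance_matches_lognormal_mean(self):
        # E[v_a] = exp(mu_a + sigma_a^2 / 2) for log-normally drawn variances
        params = make_params(n_genes=5000, n_subjects=6, mu_a=-2.0, sigma_a=0.5)
        mu, a, b = simulate_sample_means(params, np.random.default_rng(7))
        observed = ((a - 1.0) ** 2).mean()
        expected = np.exp(-2.0 + 0.5**2 / 2)
        assert observed == pytest.approx(expected, rel=0.05)


class TestResolveDESpec:
    def test_proportion_form_two_timepoints(self):
        spec = DESpec(proportion_de=0.2, log2fc=0.35)
        lam, flags = resolve_de_spec(spec, 10, 2, np.random.default_rng(0))
        assert flags.sum() == 2
        last = lam[flags, -1]
        assert sorted(last.tolist()) == [-0.35, 0.35]
        assert (lam[:, 0] == 0).all()

    def test_linear_interpolation_four_timepoints(self):
        spec = DESpec(proportion_de=0.5, log2fc=0.35)
        lam, flags = resolve_de_spec(spec, 4, 4, np.random.default_rng(1))
        g = np.flatnonzero(flags)[0]
        ramp = lam[g] / lam[g, -1]
        np.testing.assert_allclose(ramp, [0, 1 / 3, 2 / 3, 1.0])

    def test_null_spec(self):
        lam, flags = resolve_de_spec(None, 5, 3, np.random.default_rng(0))
        assert not lam.any() and not flags.any()

    def test_odd_count_extra_gene_up(self):
        spec = DESpec(proportion_de=0.3, log2fc=1.0)
        lam, flags = resolve_de_spec(spec, 10, 2, np.random.default_rng(0))
        last = lam[flags, -1]
        assert (last > 0).sum() == 2 and (last < 0).sum() == 1

    def test_pool_form(self):
        spec = DESpec(log2fc_pool=[0.5, -0.5, 1.0])
        lam, flags = resolve_de_spec(spec, 20, 2, np.random.default_rng(0))
        assert flags.sum() == 3
        assert set(np.abs(lam[flags, -1])) <= {0.5, 1.0}

    def test_explicit_missing_gene_errors(self):
        spec = DESpec(log2fc_matrix=np.array([1.0]), gene_ids=["nope"])
        with pytest.raises(ValueError, match="not in dataset"):
            resolve_de_spec(spec, 3, 2, np.random.default_rng(0), ["g1", "g2", "g3"])

    def test_explicit_form(self):
        spec = DESpec(log2fc_matrix=np.array([2.0]), gene_ids=["g2"])
        lam, flags = resolve_de_spec(spec, 3, 3, np.random.default_rng(0),
                                     ["g1", "g2", "g3"])
        np.testing.assert_allclose(lam[1], [0.0, 1.0, 2.0])
        assert flags.tolist() == [False, True, False]


class TestSimulateTrueExpression:
    def test_gamma_moments(self):
        rng = np.random.default_rng(0)
        mu = np.full((1, 1), 10.0)
        lam = np.zeros((1, 1))
        cells = np.zeros(100000, dtype=int)
        x = simulate_true_expression(mu, np.array([0.4]), lam, cells, cells, rng)
        assert x.mean() == pytest.approx(10.0, rel=0.01)
        assert x.var() == pytest.approx(0.4 * 100.0, rel=0.05)

    def test_zero_dispersion_deterministic(self):
        rng = np.random.default_rng(0)
        mu = np.array([[3.0, 7.0]])
        lam = np.zeros((1, 1))
        cells = np.array([0, 1, 1])
        x = simulate_true_expression(mu, np.array([0.0]), lam, cells,
                                     np.zeros(3, dtype=int), rng)
        np.testing.assert_array_equal(x, [[3.0, 7.0, 7.0]])

    def test_fold_change_scales_mean(self):
        rng = np.random.default_rng(1)
        mu = np.full((1, 1), 5.0)
        lam = np.array([[0.0, 1.0]])  # 2-fold at second timepoint
        cells = np.zeros(50000, dtype=int)
        tps = np.ones(50000, dtype=int)
        x = simulate_true_expression(mu, np.array([0.2]), lam, cells, tps, rng)
        assert x.mean() == pytest.approx(10.0, rel=0.02)

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            simulate_true_expression(
                np.array([[-1.0]]), np.array([0.1]), np.zeros((1, 1)),
                np.zeros(1, dtype=int), np.zeros(1, dtype=int),
                np.random.default_rng(0),
            )


class TestDrawLibrarySizes:
    def test_degenerate_limits(self):
        params = make_params(sigma_lib=0.0, lib_concentration=1e9, mu_lib=9.0)
        cell_sample = np.repeat(np.arange(8), 10)
        lib, d = draw_library_sizes(params, cell_sample, np.random.default_rng(0))
        np.testing.assert_allclose(lib, np.exp(9.0), rtol=1e-3)

    def test_shift_sum_exact(self, small_params):
        cell_sample = np.repeat(np.arange(8), 5)
        lib, d = draw_library_sizes(small_params, cell_sample,
                                    np.random.default_rng(1))
        assert d.sum() == pytest.approx(8.0, abs=1e-9)

    def test_lognormal_moments(self):
        params = make_params(mu_lib=9.0, sigma_lib=0.3, lib_concentration=1e9)
        cell_sample = np.zeros(100000, dtype=int)
        lib, _ = draw_library_sizes(params, cell_sample, np.random.default_rng(2))
        logs = np.log(lib)
        assert logs.mean() == pytest.approx(9.0, rel=0.005)
        assert logs.std() == pytest.approx(0.3, rel=0.03)

    def test_custom_mode_resamples_and_shifts(self):
        custom = np.array([1000.0, 2000.0, 4000.0])
        params = make_params(custom_lib_sizes=custom, lib_concentration=1e9)
        cell_sample = np.repeat(np.arange(8), 100)
        lib, d = draw_library_sizes(params, cell_sample, np.random.default_rng(3))
        # with shifts ~1 every draw is an original value
        assert set(np.round(lib).astype(int)) <= {1000, 2000, 4000}


class TestPoissonObserve:
    def test_total_counts_match_library(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, 1.0, size=(100, 5000))
        lib = np.full(5000, 5000.0)
        y = poisson_observe(x, lib, rng)
        assert y.sum(axis=0).mean() == pytest.approx(5000.0, rel=0.01)

    def test_single_gene_takes_library(self):
        rng = np.random.default_rng(0)
        x = np.zeros((3, 1))
        x[1, 0] = 0.25
        y = poisson_observe(x, np.array([500.0]), rng)
        assert y[0, 0] == 0 and y[2, 0] == 0
        assert y[1, 0] == pytest.approx(500, rel=0.2)

    def test_zero_library(self):
        rng = np.random.default_rng(0)
        x = np.ones((3, 1))
        y = poisson_observe(x, np.array([0.0]), rng)
        assert not y.any()

    def test_all_zero_cell_warns(self):
        rng = np.random.default_rng(0)
        x = np.zeros((2, 1))
        with pytest.warns(UserWarning, match="zero total"):
            y = poisson_observe(x, np.array([100.0]), rng)
        assert not y.any()


class TestSimulateDataset:
    def test_deterministic(self, small_params):
        a = simulate_dataset(small_params, 7)
        b = simulate_dataset(small_params, 7)
        assert (a.counts != b.counts).nnz == 0

    def test_design_shape(self):
        params = make_params(n_genes=100, n_subjects=5, n_timepoints=2,
                             cells_per_sample=200)
        sim = simulate_dataset(params, 1)
        assert sim.dataset.n_samples == 10
        assert sim.dataset.n_cells == 2000

    def test_uniform_cells_spec(self):
        params = make_params(n_genes=50, cells_per_sample=(20, 40))
        sim = simulate_dataset(params, 2)
        sizes = sim.dataset.cells_per_sample()
        assert sizes.between(20, 40).all()

    def test_null_simulation_balanced_logcpm(self):
        # library shifts off: they are sample-random, not timepoint-aligned,
        # and would dominate the Monte-Carlo error of the timepoint contrast
        params = make_params(n_genes=2000, n_subjects=6, n_timepoints=2,
                             cells_per_sample=100, lib_concentration=1e9)
        sim = simulate_dataset(params, 3)
        from screpsim.fidelity import _log_cpm

        logcpm, _ = _log_cpm(sim.counts)
        t2 = (sim.cells["timepoint"] == "t2").to_numpy()
        diff = logcpm[:, t2].mean(axis=1) - logcpm[:, ~t2].mean(axis=1)
        assert abs(diff.mean()) < 0.03

    def test_library_scaled_means_track_gene_means(self):
        # law of total expectation: per-gene mean of y * (refLib / L) is
        # proportional to the gene's share of the cell's expected expression
        params = make_params(n_genes=1000, n_subjects=6, n_timepoints=2,
                             cells_per_sample=80)
        sim = simulate_dataset(params, 8, keep_intermediates=True)
        ref = np.exp(params.mu_lib)
        y = np.asarray(sim.counts.todense(), dtype=float)
        scaled = y * (ref / sim.expected_lib_sizes)
        observed = scaled.mean(axis=1)

        # sample_means columns follow construction (appearance) order
        order = {s: i for i, s in enumerate(pd.unique(sim.cells["sample_id"]))}
        sample_of_cell = sim.cells["sample_id"].map(order).to_numpy()
        mu_cell = sim.sample_means[:, sample_of_cell]
        predicted = ref * (mu_cell / mu_cell.sum(axis=0)).mean(axis=1)
        slope = (observed @ predicted) / (predicted @ predicted)
        assert slope == pytest.approx(1.0, rel=0.03)

    def test_intermediates_retained(self, small_params):
        sim = simulate_dataset(small_params, 4, keep_intermediates=True)
        g = small_params.n_genes
        assert sim.sample_means.shape == (g, 8)
        np.testing.assert_allclose(sim.subject_factors.sum(axis=1), 4, atol=1e-9)


class TestDownsampleDataset:
    @pytest.fixture()
    def master(self):
        params = make_params(
            n_genes=100, n_subjects=10, n_timepoints=4, cells_per_sample=30,
            de_spec=DESpec(proportion_de=0.2, log2fc=1.0),
        )
        return simulate_dataset(params, 11)

    def test_subject_downsampling(self, master):
        out = downsample_dataset(master, np.random.default_rng(0), n_subjects=5)
        assert out.dataset.n_subjects == 5
        assert out.dataset.sample_table().groupby("subject_id", observed=True).size().eq(4).all()

    def test_timepoint_downsampling_keeps_endpoints(self, master):
        out = downsample_dataset(master, np.random.default_rng(0), n_timepoints=2)
        kept = set(out.dataset.cells["timepoint"].astype(str))
        assert kept == {"t1", "t4"}
        # first-to-last fold change preserved in re-sliced truth
        np.testing.assert_array_equal(out.truth_log2fc[:, -1],
                                      master.truth_log2fc[:, -1])
        assert (out.truth_log2fc[:, 0] == 0).all()

    def test_cell_downsampling_exact(self, master):
        out = downsample_dataset(master, np.random.default_rng(0),
                                 cells_per_sample=20)
        assert out.dataset.cells_per_sample().eq(20).all()

    def test_counts_are_subset(self, master):
        out = downsample_dataset(master, np.random.default_rng(1), n_subjects=3,
                                 cells_per_sample=10)
        kept = set(out.dataset.cells["cell_id"])
        orig_cols = {c: i for i, c in enumerate(master.dataset.cells["cell_id"])}
        sub_idx = [orig_cols[c] for c in out.dataset.cells["cell_id"]]
        assert (out.counts != master.counts[:, sub_idx]).nnz == 0

    def test_target_exceeds_available(self, master):
        with pytest.raises(ValueError):
            downsample_dataset(master, np.random.default_rng(0), n_subjects=11)
        with pytest.raises(ValueError):
            downsample_dataset(master, np.random.default_rng(0),
                               cells_per_sample=1000)

    def test_truth_flags_shared(self, master):
        out = downsample_dataset(master, np.random.default_rng(0), n_subjects=4)
        np.testing.assert_array_equal(out.de_flags, master.de_flags)
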