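"""Bootstrap distributions, shuffled-null invariants, empirical p-values."""

import numpy as np
import pytest

import fosnet as f
from fosnet.inference import (MetricDistribution, shuffle_correlation_matrix,
                              _metrics_of_matrices)


def _dist(values, observed=0.0, name="global_efficiency",
          source="shuffled_null"):
    return MetricDistribution(metric_name=name, source=source,
                              values=tuple(float(v) for v in values),
                              B=len(values), seed=0, observed=observed)


class TestBootstrap:
    def test_distribution_length_and_determinism(self, li_tables):
        counts, _ = li_tables
        d1 = f.bootstrap_metrics(counts, B=25, seed=7)
        d2 = f.bootstrap_metrics(counts, B=25, seed=7)
        assert {d.metric_name for d in d1} == {"transitivity",
                                               "global_efficiency"}
        for a, b in zip(d1, d2):
            assert a.B == 25 and len(a.values) == 25
            assert a.values == b.values  # bitwise reproducible

    def test_different_seeds_differ(self, li_tables):
        counts, _ = li_tables
        a = f.bootstrap_metrics(counts, B=25, seed=1)
        b = f.bootstrap_metrics(counts, B=25, seed=2)
        assert a[1].values != b[1].values

    def test_correlated_data_beats_independent_data(self, hi_config,
                                                    null_config):
        strong = f.generate_condition_counts(hi_config, "HI")
        noise = f.generate_condition_counts(null_config, "IND")
        d_strong = {d.metric_name: d for d in
                    f.bootstrap_metrics(strong, B=60, seed=3)}
        d_noise = {d.metric_name: d for d in
                   f.bootstrap_metrics(noise, B=60, seed=4)}
        assert (np.median(d_strong["global_efficiency"].as_array())
                > np.median(d_noise["global_efficiency"].as_array()))


class TestShuffledNull:
    def test_replicates_preserve_matrix_invariants(self, li_tables):
        counts, _ = li_tables
        rho, p = f.spearman_matrix(counts)
        rho_v, p_v = rho.to_numpy(), p.to_numpy()
        iu, ju = np.triu_indices(7, 1)
        base_rho = np.sort(rho_v[iu, ju])
        base_edges = (p_v[iu, ju] < 0.05).sum()
        rng = np.random.default_rng(0)
        for _ in range(200):
            r_new, p_new = shuffle_correlation_matrix(rho_v, p_v, rng)
            np.testing.assert_array_equal(r_new, r_new.T)
            np.testing.assert_array_equal(np.diag(r_new), np.ones(7))
            np.testing.assert_allclose(np.sort(r_new[iu, ju]), base_rho)
            assert (p_new[iu, ju] < 0.05).sum() == base_edges

    def test_empty_network_null_is_degenerate(self):
        rho = np.eye(4)
        p = np.ones((4, 4))
        np.fill_diagonal(p, 0.0)
        import pandas as pd
        dists = f.shuffled_null(pd.DataFrame(rho), pd.DataFrame(p), N=20,
                                seed=0)
        for d in dists:
            assert len(set(d.values)) == 1
            assert d.values[0] == d.observed

    def test_null_seed_determinism(self, hi_tables):
        counts, _ = hi_tables
        rho, p = f.spearman_matrix(counts)
        a = f.shuffled_null(rho, p, N=30, seed=5)
        b = f.shuffled_null(rho, p, N=30, seed=5)
        for x, y in zip(a, b):
            assert x.values == y.values


class TestMetricVsChance:
    def test_observed_above_all_nulls(self):
        d = _dist(np.linspace(0, 0.5, 100))
        out = f.metric_vs_chance(0.9, d, "greater")
        assert out.empirical_p == pytest.approx(1 / 101)

    def test_observed_at_median(self):
        d = _dist(np.linspace(0, 1, 101))
        out = f.metric_vs_chance(0.5, d, "greater")
        assert out.empirical_p == pytest.approx(0.5, abs=0.02)

    def test_direction_antisymmetry_identity(self):
        rng = np.random.default_rng(11)
        values = np.round(rng.normal(size=100), 2)
        for obs in (0.0, 0.37, float(values[3])):
            d = _dist(values, observed=obs)
            pg = f.metric_vs_chance(obs, d, "greater").empirical_p
            pl = f.metric_vs_chance(obs, d, "less").empirical_p
            ties = int(np.sum(np.abs(values - obs) <= 1e-12))
            assert pg + pl == pytest.approx(1 + (1 + ties) / 101)

    def test_conservative_under_exchangeable_noise(self, null_config):
        """Edge-count-preserving shuffles tie heavily with the observed
        value, so the chance test rejects at most at the nominal rate."""
        from fosnet.exact import spearman_matrix_exact
        import pandas as pd
        import fosnet.simulate as sim
        hits = 0
        n_sims = 120
        for k in range(n_sims):
            cfg = sim.SimConfig(block_structure={"IND": ()}, rho_within=0.5,
                                rho_between=0.0, seed=7000 + k)
            t = f.generate_condition_counts(cfg, "IND")
            rho, p = spearman_matrix_exact(t.values())
            dists = f.shuffled_null(pd.DataFrame(rho), pd.DataFrame(p),
                                    N=50, seed=k)
            for d in dists:
                if f.metric_vs_chance(d.observed, d,
                                      "greater").empirical_p < 0.05:
                    hits += 1
        assert hits / (2 * n_sims) <= 0.05


class TestCompareConditions:
    def test_identical_distributions_p_one(self):
        a = _dist(np.linspace(0, 1, 50), source="bootstrap")
        b = _dist(np.linspace(0, 1, 50), source="bootstrap")
        out = f.compare_conditions(a, b)
        assert out.p_value == pytest.approx(1.0)
        assert out.greater == "tie"

    def test_complete_separation_tiny_p(self):
        a = _dist(np.linspace(0, 1, 100), source="bootstrap")
        b = _dist(np.linspace(10, 11, 100), source="bootstrap")
        out = f.compare_conditions(a, b, label_a="LI", label_b="HI")
        assert out.p_value < 1e-30
        assert out.greater == "HI"

    def test_metric_name_mismatch_rejected(self):
        a = _dist([1, 2, 3], name="transitivity", source="bootstrap")
        b = _dist([1, 2, 3], name="global_efficiency", source="bootstrap")
        with pytest.raises(ValueError, match="metric mismatch"):
            f.compare_conditions(a, b)


def test_thresholded_metrics_helper_consistent_with_public_path(li_tables):
    counts, _ = li_tables
    rho, p = f.spearman_matrix(counts)
    net = f.threshold_network(rho, p, 0.05)
    via_net = f.global_metrics(net)
    via_mats = _metrics_of_matrices(rho.to_numpy(), p.to_numpy(), 0.05)
    assert via_net.transitivity == pytest.approx(via_mats.transitivity)
    assert via_net.global_efficiency == pytest.approx(
        via_mats.global_efficiency)
    assert via_net.n_edges_pos == via_mats.n_edges_pos
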