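import numpy as np
import pytest

from twinconn import (
    TwinSimParams,
    analytic_twin_g_correlation,
    compute_fc_matrix,
    average_runs,
    emit_time_series,
    generate_cohort,
    generate_study_cohort,
    vectorize_lower_triangle,
)
from twinconn.atlas import intra_network_edge_indices, scaled_atlas


def _within_pair_edge_corr(cohort):
    """Mean over edges of the across-pair correlation between co-twin values."""
    pairs = cohort.pair_indices()
    a = cohort.edges[pairs[:, 0]]
    b = cohort.edges[pairs[:, 1]]
    ac = a - a.mean(0)
    bc = b - b.mean(0)
    r = (ac * bc).sum(0) / np.sqrt((ac**2).sum(0) * (bc**2).sum(0))
    return r.mean()


class TestGenerateCohort:
    def test_degenerate_limit_identical_cotwins(self):
        syn = generate_cohort(
            TwinSimParams(n_pairs=5, node_count=8, rho=1.0, sigma=0.0,
                          shared_env=0.0, causal_edge_count=4, seed=3)
        )
        pairs = syn.cohort.pair_indices()
        a, b = pairs[:, 0], pairs[:, 1]
        assert np.allclose(syn.cohort.edges[a], syn.cohort.edges[b])
        g = syn.cohort.roster["g_raw"].to_numpy()
        assert np.allclose(g[a], g[b])

    def test_independent_limit_zero_pair_correlation(self):
        syn = generate_cohort(
            TwinSimParams(n_pairs=400, node_count=10, rho=0.0, seed=4,
                          causal_edge_count=5)
        )
        assert abs(_within_pair_edge_corr(syn.cohort)) < 0.02

    def test_moment_oracle_for_within_pair_correlation(self):
        syn = generate_cohort(
            TwinSimParams(n_pairs=500, node_count=10, rho=0.6, seed=5,
                          causal_edge_count=5)
        )
        assert _within_pair_edge_corr(syn.cohort) == pytest.approx(0.6, abs=0.03)

    def test_g_variance_matches_model(self):
        params = TwinSimParams(n_pairs=2000, node_count=10, rho=0.5, beta=0.7,
                               sigma=0.5, shared_env=0.2, causal_edge_count=5,
                               seed=6)
        syn = generate_cohort(params)
        expected = params.beta**2 + params.sigma**2 + params.shared_env
        assert np.var(syn.cohort.roster["g_raw"]) == pytest.approx(expected, rel=0.08)

    def test_fixed_seed_reproduces_cohort_exactly(self):
        p = TwinSimParams(n_pairs=10, node_count=12, seed=77, causal_edge_count=6)
        a, b = generate_cohort(p), generate_cohort(p)
        assert np.array_equal(a.cohort.edges, b.cohort.edges)
        assert a.cohort.roster.equals(b.cohort.roster)
        assert np.array_equal(a.causal_edges, b.causal_edges)
        c = generate_cohort(TwinSimParams(n_pairs=10, node_count=12, seed=78,
                                          causal_edge_count=6))
        assert not np.array_equal(a.cohort.edges, c.cohort.edges)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TwinSimParams(n_pairs=5, rho=1.2)
        with pytest.raises(ValueError):
            TwinSimParams(n_pairs=5, sigma=-1)
        with pytest.raises(ValueError):
            TwinSimParams(n_pairs=5, node_count=5, causal_edge_count=100)
        with pytest.raises(ValueError):
            TwinSimParams(n_pairs=5, causal_network="DMN")  # needs atlas

    def test_network_concentration_plants_causal_edges_inside_network(self):
        atlas = scaled_atlas(40)
        syn = generate_cohort(
            TwinSimParams(n_pairs=4, node_count=40, causal_edge_count=3,
                          causal_network="CRB", atlas=atlas, seed=8)
        )
        pool = set(intra_network_edge_indices(atlas, "CRB").tolist())
        assert set(syn.causal_edges.tolist()) <= pool


class TestAnalyticTwinCorrelation:
    def test_direct_cases(self):
        p = TwinSimParams(n_pairs=5, node_count=8, rho=0.8, beta=1.0, sigma=0.0,
                          shared_env=0.0, causal_edge_count=4)
        assert analytic_twin_g_correlation(p) == pytest.approx(0.8)
        p0 = TwinSimParams(n_pairs=5, node_count=8, rho=0.8, beta=0.0,
                           sigma=1.0, shared_env=0.0, causal_edge_count=4)
        assert analytic_twin_g_correlation(p0) == 0.0

    def test_matches_large_sample_simulation(self):
        params = TwinSimParams(n_pairs=2000, node_count=10, rho=0.45, beta=0.9,
                               sigma=0.6, shared_env=0.25, causal_edge_count=5,
                               seed=11)
        syn = generate_cohort(params)
        pairs = syn.cohort.pair_indices()
        g = syn.cohort.roster["g_raw"].to_numpy()
        emp = np.corrcoef(g[pairs[:, 0]], g[pairs[:, 1]])[0, 1]
        assert emp == pytest.approx(analytic_twin_g_correlation(params), abs=0.05)

    def test_zero_variance_rejected(self):
        p = TwinSimParams(n_pairs=5, node_count=8, beta=0.0, sigma=0.0,
                          shared_env=0.0, causal_edge_count=4)
        with pytest.raises(ValueError, match="zero variance"):
            analytic_twin_g_correlation(p)


def test_falconer_recovery_from_two_conditions():
    """h2 from generated MZ/DZ-like conditions matches the model-implied value."""
    from twinconn import adjust_cohort, falconer_h2, twin_pair_correlation

    beta, sigma = 0.8, 0.6
    rs = {}
    for rho, z in ((0.8, "MZ"), (0.2, "DZ")):
        params = TwinSimParams(n_pairs=1500, node_count=10, rho=rho, beta=beta,
                               sigma=sigma, shared_env=0.0, causal_edge_count=5,
                               zygosity=z, seed=13)
        cohort = adjust_cohort(generate_cohort(params).cohort)
        rs[z], _ = twin_pair_correlation(cohort, z, double_entry=True)
    expected = 2 * beta**2 * (0.8 - 0.2) / (beta**2 + sigma**2)
    est = falconer_h2(rs["MZ"], rs["DZ"])
    assert est.h2 == pytest.approx(expected, abs=0.08)


def test_study_cohort_shares_architecture_across_zygosities():
    syn = generate_study_cohort(n_mz=6, n_dz=4, node_count=12, seed=2)
    roster = syn.cohort.roster
    assert (roster["zygosity"] == "MZ").sum() == 12
    assert (roster["zygosity"] == "DZ").sum() == 8
    assert syn.cohort.n_edges == 66
    # co-twins share age and gender (same-sex pairs)
    for _, grp in roster.groupby("pair_id"):
        assert grp["age"].nunique() == 1
        assert grp["gender"].nunique() == 1


def test_emitted_time_series_recover_edge_profile():
    vec = np.random.default_rng(21).standard_normal(28)  # R = 8
    runs = emit_time_series(vec, n_timepoints=1500, n_runs=2, z_scale=0.3, seed=22)
    assert len(runs) == 2 and runs[0].data.shape == (1500, 8)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        avg = average_runs([compute_fc_matrix(r) for r in runs])
    recovered = vectorize_lower_triangle(avg)
    r = np.corrcoef(recovered, vec)[0, 1]
    assert r > 0.8
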