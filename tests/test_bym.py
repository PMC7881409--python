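"""The spatial convolution sampler: ICAR density, determinism, constraints,
degenerate collapses, summaries and convergence diagnostics."""

import numpy as np
import networkx as nx
import pytest

import spatrisk as sp
from spatrisk.bym import (
    _param_row,
    effective_sample_size,
    gelman_rubin,
    geweke_z,
)
from spatrisk.data import ValidationError

from .conftest import make_dataset


class TestIcarLogDensity:
    def test_constant_vector_is_flat_direction(self, iran_adj):
        n, k = iran_adj.n_areas, 1
        val = sp.icar_logdensity(np.full(n, 3.7), tau=2.0, adjacency=iran_adj)
        assert val == pytest.approx(0.5 * (n - k) * np.log(2.0))

    def test_two_area_hand_arithmetic(self):
        adj = sp.AdjacencyStructure.from_pairs(["A", "B"], [("A", "B")])
        val = sp.icar_logdensity(np.array([1.0, -1.0]), tau=1.0, adjacency=adj)
        assert val == pytest.approx(-2.0)

    def test_matches_laplacian_quadratic_form_on_cycle(self, rng):
        areas = ["a", "b", "c", "d"]
        pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
        adj = sp.AdjacencyStructure.from_pairs(areas, pairs)
        delta = rng.standard_normal(4)
        tau = 1.7
        # independent oracle: quadratic form with Q = D - W from networkx
        Q = nx.laplacian_matrix(adj.graph(), nodelist=areas).toarray()
        expect = 0.5 * (4 - 1) * np.log(tau) - 0.5 * tau * delta @ Q @ delta
        got = sp.icar_logdensity(delta, tau, adj)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_nonpositive_tau_rejected(self, iran_adj):
        with pytest.raises(ValidationError):
            sp.icar_logdensity(np.zeros(30), 0.0, iran_adj)


class TestSamplerContracts:
    def test_same_seed_bit_identical(self, chain3):
        cfg = sp.BymConfig(n_iterations=400, burn_in=100, seed=5)
        s1 = sp.fit_bym(chain3, (), cfg)
        s2 = sp.fit_bym(chain3, (), sp.BymConfig(
            n_iterations=400, burn_in=100, seed=5))
        assert np.array_equal(s1.alpha, s2.alpha)
        assert np.array_equal(s1.theta, s2.theta)
        assert np.array_equal(s1.tau, s2.tau)

    def test_delta_draws_sum_to_zero(self, short_male_sample):
        assert np.abs(short_male_sample.delta.sum(axis=1)).max() < 1e-8

    def test_positive_scales_and_risks(self, short_male_sample):
        assert (short_male_sample.sigma > 0).all()
        assert (short_male_sample.tau > 0).all()
        assert (short_male_sample.theta > 0).all()

    def test_clamped_random_effects_collapse_to_pooled_ratio(self, chain3):
        cfg = sp.BymConfig(
            n_iterations=6000, burn_in=1000, seed=3, use_u=False, use_delta=False
        )
        s = sp.fit_bym(chain3, (), cfg)
        pooled = s.observed.sum() / s.expected.sum()
        post = np.exp(s.alpha[s.retained()])
        # posterior concentrates near the pooled ratio
        assert post.mean() == pytest.approx(pooled, rel=0.03)
        assert np.allclose(s.u, 0.0) and np.allclose(s.delta, 0.0)

    def test_disconnected_graph_refused(self):
        adj = sp.AdjacencyStructure.from_pairs(
            ["A", "B", "C", "D"], [("A", "B"), ("C", "D")]
        )
        ds = make_dataset([5, 6, 7, 8], [5.0, 6.0, 7.0, 8.0])
        ds = sp.StudyDataset(
            records=[
                sp.ProvinceRecord(a, "both", 5, 5.0) for a in adj.areas
            ],
            adjacency=adj,
        )
        with pytest.raises(sp.bym.ConfigurationError, match="disconnected"):
            sp.fit_bym(ds, (), sp.BymConfig(n_iterations=200, burn_in=50))

    def test_prior_recovery_under_flat_likelihood(self):
        # with negligible expected counts the likelihood carries no
        # information and alpha's draws must match its Normal(0, 100) prior
        adj = sp.lattice_adjacency(2, 2)
        ds = sp.StudyDataset(
            records=[sp.ProvinceRecord(a, "both", 0, 1e-30) for a in adj.areas],
            adjacency=adj,
        )
        cfg = sp.BymConfig(n_iterations=22_000, burn_in=2_000, seed=11)
        s = sp.fit_bym(ds, (), cfg)
        sd = s.alpha[s.retained()].std()
        assert abs(sd - 10.0) / 10.0 < 0.10


class TestSummaries:
    def test_surface_invariants(self, short_male_sample):
        surface, params = sp.summarize_posterior(short_male_sample)
        t = surface.table
        assert (t.rr_ci_low <= t.rr_median).all()
        assert (t.rr_median <= t.rr_ci_high).all()
        assert t.exceedance_prob.between(0, 1).all()

    def test_symmetric_beta_flagged_not_significant(self, rng):
        draws = rng.standard_normal(2000) * 0.2
        row = _param_row("beta_uer", draws, exp_scale=True)
        assert not row["significant"]
        assert row["exp_ci_low"] < 1.0 < row["exp_ci_high"]

    def test_identical_draws_collapse_interval(self):
        row = _param_row("beta_uer", np.full(500, 0.3), exp_scale=True)
        assert row["exp_ci_low"] == pytest.approx(row["exp_ci_high"])

    def test_too_few_retained_draws_refused(self, chain3):
        cfg = sp.BymConfig(n_iterations=150, burn_in=100, seed=2)
        s = sp.fit_bym(chain3, (), cfg)
        with pytest.raises(ValidationError, match="retained"):
            sp.summarize_posterior(s)


class TestDiagnostics:
    def test_iid_normal_chains_have_unit_rhat(self, rng):
        chains = [rng.standard_normal(500) for _ in range(4)]
        r = gelman_rubin(chains)
        assert 0.99 <= r <= 1.05

    def test_disjoint_chains_have_large_rhat(self, rng):
        a = rng.standard_normal(500)
        b = rng.standard_normal(500) + 50.0
        assert gelman_rubin([a, b]) > 1.1

    def test_constant_chain_flagged_degenerate(self, short_male_sample):
        s = short_male_sample
        frozen = sp.PosteriorSample(
            areas=s.areas, covariate_names=[], alpha=np.zeros(1000),
            beta=s.beta[:1000], u=s.u[:1000], delta=s.delta[:1000],
            sigma=np.ones(1000), tau=np.ones(1000), theta=s.theta[:1000],
            deviance_raw=s.deviance_raw[:1000], deviance_sat=s.deviance_sat[:1000],
            observed=s.observed, expected=s.expected,
            config=sp.BymConfig(n_iterations=1000, burn_in=0, seed=0),
        )
        diag = sp.convergence_diagnostics(frozen)
        assert diag.set_index("parameter").loc["alpha", "degenerate"]

    def test_fitted_chain_passes_geweke(self, short_male_sample):
        diag = sp.convergence_diagnostics(short_male_sample)
        z = diag.set_index("parameter").loc["alpha", "geweke_z"]
        assert abs(z) < 4.0

    def test_ess_of_iid_draws_near_n(self, rng):
        x = rng.standard_normal(2000)
        assert effective_sample_size(x) == pytest.approx(2000, rel=0.25)

    def test_geweke_needs_enough_draws(self):
        with pytest.raises(ValidationError):
            geweke_z(np.arange(12.0))
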