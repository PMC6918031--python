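"""Variance decomposition: identities, dilution correction, Shapley, keys."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxvar.contributions import (
    ContributionProfile,
    FluxTable,
    InsufficientDataError,
    build_flux_tables,
    classify_key_contributors,
    contribution_values,
    dilution_correct,
    shapley_contributions,
)


def random_table(n_species=3, n_samples=20, seed=0, constant_env=False):
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(n_samples, n_species))
    env = np.full(n_samples, 2.0) if constant_env else rng.normal(size=n_samples)
    return FluxTable(
        metabolite_id="met",
        species_ids=[f"s{i}" for i in range(n_species)],
        m_star=m,
        m_env=env,
        M=m.sum(axis=1) + env,
    )


class TestDilutionCorrect:
    def test_no_dilution_is_cumulative_sum(self):
        series = np.array([0.5, -1.0, 2.0])
        assert dilution_correct(series, 0.0) == pytest.approx(series.sum())

    def test_two_step_example(self):
        assert dilution_correct([1.0, 1.0], 0.1) == pytest.approx(1.9)

    def test_zero_series(self):
        assert dilution_correct(np.zeros(10), 0.3) == 0.0

    def test_matches_diluting_pool_simulation(self):
        """Oracle: deposit each amount into a pool diluted by d per step; the
        surviving mass equals the dilution-corrected cumulative flux."""
        rng = np.random.default_rng(5)
        series = rng.normal(size=12)
        d = 0.07
        pool = 0.0
        for amount in series:
            pool = pool * (1 - d) + amount
        assert dilution_correct(series, d) == pytest.approx(pool, rel=1e-12)

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=8),
        st.floats(0, 0.99),
        st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, series, d, scale):
        series = np.array(series)
        lhs = dilution_correct(scale * series, d)
        rhs = scale * dilution_correct(series, d)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestContributionValues:
    def test_covariance_equivalence_and_conservation(self):
        """c_i = cov(m_i, M) and sum c_i + c_env = var(M), both to 1e-10."""
        table = random_table(seed=3)
        profile = contribution_values(table)
        var_M = np.var(table.M, ddof=1)
        assert profile.var_M == pytest.approx(var_M, rel=1e-10)
        assert profile.c.sum() + profile.c_env == pytest.approx(
            var_M, rel=1e-10
        )
        for i in range(3):
            direct_cov = np.cov(table.m_star[:, i], table.M, ddof=1)[0, 1]
            assert profile.c[i] == pytest.approx(direct_cov, rel=1e-10)

    def test_sole_producer_gets_relative_one(self):
        """A species solely responsible for variation under constant inflow
        carries the whole variance."""
        rng = np.random.default_rng(1)
        n = 30
        m = np.zeros((n, 4))
        m[:, 2] = rng.normal(2.0, 1.0, size=n)
        m[:, 0] = 1.0  # constant activity elsewhere
        table = FluxTable("met", ["a", "b", "c", "d"], m,
                          np.full(n, 3.0), m.sum(axis=1) + 3.0)
        profile = contribution_values(table)
        assert profile.relative[2] == pytest.approx(1.0, rel=1e-12)
        assert profile.relative[[0, 1, 3]] == pytest.approx(0.0, abs=1e-12)
        assert profile.key_contributors == {"c"}

    def test_constant_flux_species_contributes_nothing(self):
        table = random_table(seed=9)
        table.m_star[:, 1] = 5.0
        table.M = table.m_star.sum(axis=1) + table.m_env
        profile = contribution_values(table)
        assert profile.c[1] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples(self):
        table = random_table(n_samples=2, seed=0)
        with pytest.raises(InsufficientDataError):
            contribution_values(table)

    def test_zero_variance_sentinel(self):
        n = 10
        table = FluxTable("met", ["a"], np.ones((n, 1)), np.ones(n),
                          np.full(n, 2.0))
        profile = contribution_values(table)
        assert profile.var_M == 0.0
        assert np.isnan(profile.relative).all()


class TestShapley:
    def test_single_species_closed_form(self):
        """With one species the only marginal is var(m1) + 2 cov(m1, env)."""
        rng = np.random.default_rng(2)
        m = rng.normal(size=(25, 1))
        env = rng.normal(size=25)
        table = FluxTable("met", ["s0"], m, env, m[:, 0] + env)
        shap = shapley_contributions(table, n_orderings=10, seed=0)
        expected = np.var(m[:, 0], ddof=1) + 2 * np.cov(m[:, 0], env, ddof=1)[0, 1]
        assert shap[0] == pytest.approx(expected, rel=1e-10)

    def test_exhaustive_matches_analytic(self):
        """Full enumeration over 3! orderings reproduces the analytic
        decomposition exactly under constant inflow."""
        table = random_table(n_species=3, seed=4, constant_env=True)
        profile = contribution_values(table)
        shap = shapley_contributions(table, n_orderings=6, seed=0)
        np.testing.assert_allclose(shap, profile.c, rtol=1e-10)

    def test_sampling_error_shrinks_with_orderings(self):
        table = random_table(n_species=8, n_samples=40, seed=6,
                             constant_env=True)
        analytic = contribution_values(table).c
        errors = []
        for n_ord in (30, 300, 3000):
            shap = shapley_contributions(table, n_orderings=n_ord, seed=12)
            errors.append(float(np.sum((shap - analytic) ** 2)))
        assert errors[2] < errors[0]


class TestKeyContributors:
    def _profile(self, c, c_env=0.0):
        c = np.asarray(c, dtype=float)
        var_M = c.sum() + c_env
        return ContributionProfile(
            "met", [f"s{i}" for i in range(len(c))], c, c_env, var_M,
            c / var_M if var_M else c * np.nan,
            c_env / var_M if var_M else float("nan"), set(),
        )

    def test_threshold_rule(self):
        prof = self._profile([0.5, 0.4, 0.05, 0.05])
        assert classify_key_contributors(prof, 0.10) == {"s0", "s1"}

    def test_sole_positive_contributor_always_key(self):
        prof = self._profile([0.0, 0.7, 0.0])
        assert classify_key_contributors(prof) == {"s1"}

    def test_negative_contributor_excluded(self):
        prof = self._profile([2.0, -5.0, 0.3])
        keys = classify_key_contributors(prof)
        assert "s1" not in keys
        assert "s0" in keys

    def test_all_nonpositive_warns_empty(self):
        prof = self._profile([-1.0, -0.2, 0.0])
        with pytest.warns(UserWarning, match="no positive contributions"):
            assert classify_key_contributors(prof) == set()


class TestBuildFluxTables:
    def test_reconstruction_identity(self, mini_traces):
        """Per sample, sum m_i* + m_env reproduces the final concentration."""
        tables = build_flux_tables(mini_traces)
        for table in tables.values():
            recon = table.m_star.sum(axis=1) + table.m_env
            scale = np.maximum(np.abs(table.M), 1.0)
            assert np.max(np.abs(recon - table.M) / scale) < 1e-6

    def test_constant_inflow_gives_zero_env_contribution(self, mini_traces):
        """All runs share one inflow, so m_env is constant across samples and
        c_env vanishes for every metabolite."""
        tables = build_flux_tables(mini_traces)
        for table in tables.values():
            assert np.ptp(table.m_env) == pytest.approx(0.0, abs=1e-9)
            profile = contribution_values(table)
            assert profile.c_env == pytest.approx(0.0, abs=1e-12)

    def test_single_step_no_dilution_equals_raw_amounts(self, toy_community):
        from fluxvar.chemostat import CommunityState, SimParams, run_simulation

        models, env = toy_community
        params = SimParams(n_steps=1, D=0.0)
        traces = []
        for total in (0.02, 0.05, 0.08):
            init = CommunityState(
                0.0, np.full(4, total / 4), env.initial_concentrations.copy()
            )
            traces.append(run_simulation(models, init, env, params))
        tables = build_flux_tables(traces)
        for met, table in tables.items():
            j = traces[0].env_metabolite_ids.index(met)
            for s, tr in enumerate(traces):
                np.testing.assert_allclose(
                    table.m_star[s], tr.exchange[0, :, j], atol=1e-15
                )

    def test_serialization_round_trip(self, tmp_path):
        """Tables (and profiles with negative / >1 relative values) survive a
        TSV round-trip."""
        rng = np.random.default_rng(0)
        m = np.column_stack([rng.normal(size=15), -0.99 * rng.normal(size=15)])
        m[:, 1] = -0.95 * m[:, 0] + 0.01 * rng.normal(size=15)
        env = np.full(15, 1.0)
        table = FluxTable("succ_like", ["p", "q"], m, env, m.sum(axis=1) + env)
        path = tmp_path / "succ_like.tsv"
        table.save(path)
        loaded = FluxTable.load(path)
        np.testing.assert_allclose(loaded.m_star, table.m_star, rtol=1e-12)
        profile = contribution_values(loaded)
        assert profile.relative[0] > 1.0  # masked producer motif
        assert profile.relative[1] < 0.0  # compensating motif
        out = tmp_path / "profile.tsv"
        profile.save(out)
        assert "succ_like" in out.read_text()
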