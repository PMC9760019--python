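import warnings

import numpy as np
import pandas as pd
import pytest

from isospec.errors import DomainError, SchemaError
from isospec.mixing import (
    DietPosterior,
    DiscriminationFactor,
    MCMCSettings,
    Sources,
    consumer_matrix,
    fit_mixing_model,
    posterior_summary,
    sources_from_table,
    tdf_from_table,
)

TDF0 = [DiscriminationFactor("d13C", 0.0, 0.0), DiscriminationFactor("d15N", 0.0, 0.0)]


def three_sources(sd=0.5):
    mu = np.array([[-35.0, 12.0], [-38.0, 9.0], [-32.0, 8.0]])
    return Sources(names=("a", "b", "c"), mu=mu, sd=np.full((3, 2), sd),
                   n=np.array([5, 5, 5]))


def algebraic_mix(sources, x):
    """Solve the 2-isotope + sum-to-one linear system exactly (J=3)."""
    A = np.vstack([sources.mu.T, np.ones(3)])
    return np.linalg.solve(A, np.array([x[0], x[1], 1.0]))


class TestInputs:
    def test_sources_round_trip(self, tmp_path):
        src = three_sources()
        table = pd.DataFrame([
            {"source": n, "isotope": iso, "mean": src.mu[j, k], "sd": src.sd[j, k], "n": 5}
            for j, n in enumerate(src.names)
            for k, iso in enumerate(("d13C", "d15N"))
        ])
        path = tmp_path / "sources.csv"
        table.to_csv(path, index=False)
        from isospec.mixing import read_sources_csv

        back = read_sources_csv(path)
        assert back.names == src.names
        assert np.allclose(back.mu, src.mu) and np.allclose(back.sd, src.sd)

    def test_missing_isotope_row_is_schema_error(self):
        table = pd.DataFrame({"source": ["a"], "isotope": ["d13C"],
                              "mean": [-35.0], "sd": [1.0]})
        with pytest.raises(SchemaError, match="d15N"):
            sources_from_table(table)

    def test_negative_sd_rejected(self):
        with pytest.raises(DomainError):
            Sources(names=("a",), mu=np.array([[-35.0, 12.0]]),
                    sd=np.array([[-1.0, 1.0]]), n=np.array([5]))
        with pytest.raises(DomainError):
            DiscriminationFactor("d13C", 0.4, -0.1)

    def test_consumer_matrix_requires_single_tissue(self, tiny_dataset):
        with pytest.raises(DomainError, match="one row per individual"):
            consumer_matrix(tiny_dataset)
        ids, x = consumer_matrix(tiny_dataset, tissue="muscle")
        assert ids == ["U1", "U2"] and x.shape == (2, 2)


class TestFit:
    def test_single_source_diet_is_one_exactly(self):
        src = Sources(names=("only",), mu=np.array([[-35.0, 10.0]]),
                      sd=np.array([[1.0, 1.0]]), n=np.array([5]))
        post = fit_mixing_model((["c1", "c2"], np.array([[-34.0, 12.0], [-35.0, 13.0]])),
                                src, TDF0, MCMCSettings(iterations=200, thin=1))
        assert np.all(post.individual_draws == 1.0)
        assert np.all(post.population_draws == 1.0)
        assert post.converged
        s = posterior_summary(post)
        ind = s[s.individual_id == "c1"]
        assert (ind["mean"] == 1.0).all() and (ind["lo"] == 1.0).all() and (ind["hi"] == 1.0).all()

    def test_exact_solution_limit(self):
        src = three_sources(sd=1e-3)
        p_true = np.array([0.5, 0.3, 0.2])
        x = p_true @ src.mu
        post = fit_mixing_model(
            (["c1"], x[None, :]), src, TDF0,
            MCMCSettings(chains=3, iterations=8000, thin=4, seed=3,
                         sigma_res_fixed=1e-3, sigma_re_fixed=0.0))
        est = post.point_estimate()[0]
        assert np.allclose(est, algebraic_mix(src, x), atol=0.05)
        assert np.allclose(est, p_true, atol=0.05)

    def test_zero_random_effect_shares_one_diet(self):
        src = three_sources(sd=1.0)
        rng = np.random.default_rng(4)
        x = np.array([0.4, 0.35, 0.25]) @ src.mu + rng.normal(0, 0.4, size=(6, 2))
        post = fit_mixing_model(
            ([f"c{i}" for i in range(6)], x), src, TDF0,
            MCMCSettings(chains=3, iterations=6000, thin=3, seed=1, sigma_re_fixed=0.0))
        est = post.point_estimate()
        # σ_RE = 0 collapses all individuals onto the population diet
        assert np.max(np.abs(est - est.mean(axis=0))) < 1e-12
        assert np.allclose(post.individual_draws[:, :, 0, :], post.population_draws)

    def test_label_permutation_equivariance(self):
        src = three_sources(sd=1.0)
        perm = [2, 0, 1]
        src_perm = Sources(names=tuple(src.names[j] for j in perm),
                           mu=src.mu[perm], sd=src.sd[perm], n=src.n[perm])
        x = np.array([[-35.0, 10.0], [-34.0, 10.5], [-36.0, 10.3]])
        settings = MCMCSettings(chains=3, iterations=8000, thin=4, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_mixing_model((["1", "2", "3"], x), src, TDF0, settings)
            b = fit_mixing_model((["1", "2", "3"], x), src_perm, TDF0, settings)
        pa = {n: m for n, m in zip(a.source_names,
                                   a.population_draws.reshape(-1, 3).mean(axis=0))}
        pb = {n: m for n, m in zip(b.source_names,
                                   b.population_draws.reshape(-1, 3).mean(axis=0))}
        for name in pa:
            assert pa[name] == pytest.approx(pb[name], abs=0.05)

    def test_simplex_closure_of_all_draws(self):
        src = three_sources(sd=1.0)
        post = fit_mixing_model(
            (["c1", "c2"], np.array([[-35.0, 10.0], [-34.0, 10.5]])), src, TDF0,
            MCMCSettings(chains=2, iterations=2000, thin=2, seed=0))
        draws = post.individual_draws
        assert np.all(draws >= 0)
        assert np.allclose(draws.sum(axis=-1), 1.0, atol=1e-9)

    def test_collinear_sources_warn(self):
        mu = np.array([[-35.0, 12.0], [-35.0, 12.0]])
        src = Sources(names=("a", "b"), mu=mu, sd=np.ones((2, 2)), n=np.array([5, 5]))
        with pytest.warns(UserWarning, match="not identifiable"):
            fit_mixing_model((["c1"], np.array([[-35.0, 12.0]])), src, TDF0,
                             MCMCSettings(chains=2, iterations=1000, thin=2, seed=0))

    def test_underdetermined_sources_warn(self, recovery_study):
        cfg, (ds, src_tbl, _, _) = recovery_study
        from isospec.simulate import tdf_table

        with pytest.warns(UserWarning, match="underdetermined"):
            fit_mixing_model(ds, sources_from_table(src_tbl),
                             tdf_from_table(tdf_table(cfg)),
                             MCMCSettings(chains=2, iterations=600, thin=2, seed=0),
                             site="S1", tissue="muscle")

    def test_dimension_mismatch_is_schema_error(self):
        src = three_sources()
        with pytest.raises(SchemaError):
            fit_mixing_model((["c1"], np.array([[-35.0, 10.0]])), src,
                             [DiscriminationFactor("d13C", 0.0, 0.0)])


class TestSummary:
    def _degenerate_posterior(self):
        draws = np.full((2, 10, 3, 4), 0.25)
        return DietPosterior(
            individual_draws=draws, population_draws=np.full((2, 10, 4), 0.25),
            sigma_re_draws=np.zeros((2, 10)), sigma_res_draws=np.zeros((2, 10, 2)),
            individual_ids=["a", "b", "c"], source_names=list("wxyz"),
            isotopes=["d13C", "d15N"],
            diagnostics=pd.DataFrame({"param": [], "rhat": [], "ess": []}),
            converged=True)

    def test_degenerate_posterior_zero_width_intervals(self):
        s = posterior_summary(self._degenerate_posterior(), level=0.9)
        assert np.allclose(s["mean"], 0.25)
        assert np.allclose(s["lo"], 0.25) and np.allclose(s["hi"], 0.25)
        assert np.allclose(s["sd"], 0.0)

    def test_unconverged_requires_force(self):
        post = self._degenerate_posterior()
        post.converged = False
        with pytest.raises(DomainError, match="force"):
            posterior_summary(post)
        assert len(posterior_summary(post, force=True)) == 16

    def test_bad_level_rejected(self):
        with pytest.raises(DomainError):
            posterior_summary(self._degenerate_posterior(), level=1.5)
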