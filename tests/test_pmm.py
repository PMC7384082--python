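"""Design construction, Gibbs sampler correctness, diagnostics, selection."""

import numpy as np
import pandas as pd
import pytest

from tpcevo.phylo import PhyloCovariance
from tpcevo.pmm import (
    ModelSpec,
    ModelSummary,
    build_design,
    compute_dic,
    compute_ess,
    compute_psrf,
    decompose_correlations,
    gibbs_sample,
    hpd_interval,
    phylogenetic_heritability,
    run_model,
    select_model,
)
from tpcevo.synthetic_data import simulate_traits, simulate_tree
from tpcevo.phylo import phylo_covariance


def _star(m):
    taxa = tuple(f"t{i+1}" for i in range(m))
    return PhyloCovariance(taxa=taxa, A=np.eye(m), A_inv=np.eye(m))


def _toy_df(pc, k=2, seed=0, **kw):
    G = kw.pop("G", 0.5 * np.eye(k))
    R = kw.pop("R", 0.5 * np.eye(k))
    names = [f"tr{j}" for j in range(k)]
    df, truth = simulate_traits(pc, G, R, response_names=names, seed=seed,
                                **kw)
    return df, truth, tuple(names)


class TestDesign:
    def test_intercepts_only_column_count(self, small_phylo):
        df, _, names = _toy_df(small_phylo)
        d = build_design(df, small_phylo, "intercepts_only",
                         response_cols=names)
        # one intercept column per response in the stacked layout
        assert d.X.shape[1] == 1
        assert d.X.shape[1] * d.k == 2

    def test_latitude_poly2_adds_two_columns_per_response(self, small_phylo):
        df, _, names = _toy_df(small_phylo)
        d = build_design(df, small_phylo, "latitude_poly2",
                         response_cols=names)
        assert d.X.shape[1] == 3
        assert d.col_groups == {"latitude": [1, 2]}

    def test_replicate_tpcs_share_one_species_effect(self):
        pc = _star(3)
        df, _, names = _toy_df(pc, tpcs_per_species=2, seed=1)
        d = build_design(df, pc, "intercepts_only", response_cols=names)
        assert d.n == 6
        # incidence maps both observations of a species to the same index
        counts = np.bincount(d.species_idx, minlength=3)
        assert list(counts) == [2, 2, 2]

    def test_missing_covariate_rows_dropped(self, small_phylo):
        df, _, names = _toy_df(small_phylo)
        df.loc[df.index[:3], "latitude"] = np.nan
        d = build_design(df, small_phylo, "abs_latitude",
                         response_cols=names)
        assert d.n_dropped == 3

    def test_unknown_taxon_rejected(self, small_phylo):
        df, _, names = _toy_df(small_phylo)
        df.loc[df.index[0], "taxon_id"] = "intruder"
        with pytest.raises(KeyError, match="intruder"):
            build_design(df, small_phylo, response_cols=names)


class TestSampler:
    def test_gls_closed_form_in_degenerate_mode(self):
        # G pinned at zero, no missing data, no measurement error: the
        # fixed-effect posterior mean must match the GLS solution, which
        # for a shared per-response design equals per-response OLS
        rng = np.random.default_rng(3)
        pc = _star(30)
        df, truth, names = _toy_df(pc, seed=3, G=np.zeros((2, 2)),
                                   R=np.array([[1.0, 0.6], [0.6, 1.0]]),
                                   latitude_slope_design=True,
                                   beta=np.array([[1.0, -2.0], [0.5, 0.8]]))
        d = build_design(df, pc, "abs_latitude", response_cols=names)
        chain = gibbs_sample(d, 3000, 500, 2, seed=9, fix_g_zero=True)
        beta_hat = np.linalg.lstsq(d.X, d.Y, rcond=None)[0]
        np.testing.assert_allclose(chain.beta.mean(0), beta_hat, atol=0.05)

    def test_determinism_same_seed_same_stream(self, small_phylo):
        df, _, names = _toy_df(small_phylo, seed=5)
        d = build_design(df, small_phylo, response_cols=names)
        c1 = gibbs_sample(d, 400, 100, 2, seed=21)
        c2 = gibbs_sample(d, 400, 100, 2, seed=21)
        assert np.array_equal(c1.beta, c2.beta)
        assert np.array_equal(c1.G, c2.G)
        assert np.array_equal(c1.deviance, c2.deviance)

    def test_draws_are_symmetric_positive_definite(self, small_phylo):
        df, _, names = _toy_df(small_phylo, seed=6)
        d = build_design(df, small_phylo, response_cols=names)
        c = gibbs_sample(d, 600, 100, 2, seed=2)
        for M in np.concatenate([c.G, c.R]):
            np.testing.assert_allclose(M, M.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(M) > 0)

    def test_extreme_heritability_recovered(self):
        # all variance at the species level -> posterior h2 near 1
        tree = simulate_tree(50, seed=2)
        pc = phylo_covariance(tree)
        df, _, names = _toy_df(pc, seed=2, G=np.eye(2), R=1e-6 * np.eye(2),
                               tpcs_per_species=2)
        d = build_design(df, pc, response_cols=names)
        spec = ModelSpec(n_chains=2, n_iter=2000, burn_in=500, thin=2,
                         seed=4)
        samples, _ = run_model(d, spec)
        h2 = phylogenetic_heritability(samples)
        for v in h2.values():
            assert v["mean"] > 0.8

    def test_weak_data_posterior_stays_diffuse(self):
        # under the weakly informative variance prior, 3 observations
        # leave the heritable-variance posterior orders of magnitude
        # wider than 100 observations do (documents weak-data behaviour)
        pc3, pc100 = _star(3), _star(100)
        spreads = {}
        for label, pc in (("weak", pc3), ("strong", pc100)):
            df, _, names = _toy_df(pc, seed=8, k=1, G=np.eye(1),
                                   R=np.eye(1), tpcs_per_species=2)
            d = build_design(df, pc, response_cols=names)
            c = gibbs_sample(d, 3000, 500, 2, seed=5)
            g = c.G[:, 0, 0]
            spreads[label] = np.percentile(g, 97.5) / np.percentile(g, 2.5)
        assert spreads["weak"] > 10 * spreads["strong"]
        assert spreads["strong"] < 30

    def test_mar_imputation_uses_correlated_trait(self):
        # trait 1 correlated 0.9 with trait 0; masking 20% of trait 1
        # still lets the sampler reconstruct it from trait 0
        pc = _star(50)
        C = np.array([[1.0, 0.9], [0.9, 1.0]])
        df, truth, names = _toy_df(pc, seed=9, G=np.zeros((2, 2)), R=C,
                                   tpcs_per_species=2)
        truth_vals = df[names[1]].to_numpy().copy()
        rng = np.random.default_rng(4)
        mask = rng.choice(len(df), size=len(df) // 5, replace=False)
        df.loc[df.index[mask], names[1]] = np.nan
        d = build_design(df, pc, response_cols=names)
        c = gibbs_sample(d, 2000, 500, 2, seed=6)
        imput = c.y_missing.mean(0)
        r = np.corrcoef(imput, truth_vals[np.sort(mask)])[0, 1]
        assert r > 0.6


class TestDiagnostics:
    def test_psrf_identical_chains(self):
        x = np.random.default_rng(0).standard_normal(500)
        assert compute_psrf(np.stack([x, x])) == pytest.approx(
            np.sqrt(499 / 500))

    def test_psrf_separated_chains(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(5, 1, 1000)
        assert compute_psrf(np.stack([a, b])) > 1.5

    def test_psrf_requires_two_chains(self):
        with pytest.raises(ValueError):
            compute_psrf(np.ones((1, 100)))

    def test_ess_independent_draws(self):
        x = np.random.default_rng(2).standard_normal(1000)
        assert 800 < compute_ess(x) < 1200

    def test_ess_ar1_closed_form(self):
        rng = np.random.default_rng(3)
        rho, n = 0.9, 20000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert expected / 1.5 < compute_ess(x) < expected * 1.5

    def test_ess_constant_chain(self):
        with pytest.warns(UserWarning):
            assert compute_ess(np.ones(100)) == 0.0

    def test_dic_degenerate_zero_variance(self):
        dic, p_d, mean_dev = compute_dic(np.full(50, 123.4), 123.4)
        assert p_d == pytest.approx(0.0)
        assert dic == pytest.approx(123.4)

    def test_dic_conjugate_normal_mean_pd(self):
        # y ~ N(mu, 1), flat prior: posterior mu ~ N(ybar, 1/n) and the
        # effective parameter count pD is 1
        rng = np.random.default_rng(5)
        y = rng.normal(2.0, 1.0, 40)
        mus = rng.normal(y.mean(), 1 / np.sqrt(len(y)), 4000)
        dev = np.array([np.sum((y - mu) ** 2) + len(y) * np.log(2 * np.pi)
                        for mu in mus])
        dev_at_mean = (np.sum((y - mus.mean()) ** 2)
                       + len(y) * np.log(2 * np.pi))
        _, p_d, _ = compute_dic(dev, dev_at_mean)
        assert p_d == pytest.approx(1.0, abs=0.25)

    def test_hpd_shortest_interval(self):
        x = np.concatenate([np.zeros(97), [50, 60, 70]])
        lo, hi = hpd_interval(x, 0.95)
        assert lo == 0 and hi == 0


class TestSummaries:
    def _summary(self, name, dic, hpds, groups, cols, n_cols):
        beta_hpd = {}
        beta_mean = {}
        for (c, r), iv in hpds.items():
            beta_hpd[(c, r)] = iv
            beta_mean[(c, r)] = float(np.mean(iv))
        return ModelSummary(name=name, dic=dic, dic_per_chain=[dic],
                            psrf={}, ess={}, beta_mean=beta_mean,
                            beta_hpd=beta_hpd, col_groups=groups,
                            col_names=cols, response_names=("a", "b"),
                            n_fixed_columns=n_cols)

    def test_all_zero_covariate_model_excluded(self):
        base = self._summary("intercepts_only", 100.0,
                             {("intercept", "a"): (0.5, 1.5),
                              ("intercept", "b"): (0.5, 1.5)},
                             {}, ["intercept"], 2)
        useless = self._summary("lat", 90.0,
                                {("intercept", "a"): (0.5, 1.5),
                                 ("intercept", "b"): (0.5, 1.5),
                                 ("lat", "a"): (-1.0, 1.0),
                                 ("lat", "b"): (-0.5, 0.5)},
                                {"lat": [1]}, ["intercept", "lat"], 4)
        assert select_model([base, useless]).name == "intercepts_only"

    def test_one_strong_response_retains_model(self):
        base = self._summary("intercepts_only", 100.0,
                             {("intercept", "a"): (0.5, 1.5)},
                             {}, ["intercept"], 2)
        strong = self._summary("lat", 90.0,
                               {("intercept", "a"): (0.5, 1.5),
                                ("lat", "a"): (0.2, 1.0),
                                ("lat", "b"): (-0.5, 0.5)},
                               {"lat": [1]}, ["intercept", "lat"], 4)
        assert select_model([base, strong]).name == "lat"

    def test_single_candidate_returned(self):
        only = self._summary("intercepts_only", 10.0,
                             {("intercept", "a"): (0.5, 1.5)},
                             {}, ["intercept"], 2)
        assert select_model([only]) is only

    def test_dic_tie_prefers_simpler(self):
        base = self._summary("intercepts_only", 100.3,
                             {("intercept", "a"): (0.5, 1.5)},
                             {}, ["intercept"], 2)
        rich = self._summary("lat", 100.0,
                             {("intercept", "a"): (0.5, 1.5),
                              ("lat", "a"): (0.2, 1.0)},
                             {"lat": [1]}, ["intercept", "lat"], 4)
        assert select_model([base, rich]).name == "intercepts_only"

    def test_correlations_diagonal_case(self, small_phylo):
        df, _, names = _toy_df(small_phylo, seed=12)
        d = build_design(df, small_phylo, response_cols=names)
        spec = ModelSpec(n_chains=2, n_iter=800, burn_in=200, thin=2, seed=3)
        samples, _ = run_model(d, spec)
        corr = decompose_correlations(samples)
        for pair in corr.values():
            for key in ("r_her", "r_res", "r_phe"):
                assert -1.0 <= pair[key]["mean"] <= 1.0
                lo, hi = pair[key]["hpd"]
                assert lo <= hi
        # i = j would give exactly 1; verified directly on the draws
        G = samples.merged("G")
        np.testing.assert_allclose(
            G[:, 0, 0] / np.sqrt(G[:, 0, 0] * G[:, 0, 0]), 1.0)

    def test_heritability_equal_components_is_half(self, small_phylo):
        df, _, names = _toy_df(small_phylo, seed=13)
        d = build_design(df, small_phylo, response_cols=names)
        spec = ModelSpec(n_chains=2, n_iter=400, burn_in=100, thin=2, seed=7)
        samples, _ = run_model(d, spec)
        for c in samples.chains:
            c.R = c.G.copy()  # force G_ii == R_ii in every draw
        h2 = phylogenetic_heritability(samples)
        for v in h2.values():
            assert v["mean"] == pytest.approx(0.5, abs=1e-12)

    def test_heritability_warns_off_intercepts_model(self, small_phylo):
        df, _, names = _toy_df(small_phylo, seed=14)
        d = build_design(df, small_phylo, "abs_latitude",
                         response_cols=names)
        spec = ModelSpec(fixed_effects="abs_latitude", n_chains=2,
                         n_iter=400, burn_in=100, thin=2, seed=8)
        samples, _ = run_model(d, spec)
        with pytest.warns(UserWarning, match="intercepts-only"):
            phylogenetic_heritability(samples)

    def test_well_mixed_chains_pass_convergence_thresholds(self, small_phylo):
        tree = simulate_tree(60, seed=21)
        pc = phylo_covariance(tree)
        df, _, names = _toy_df(pc, seed=15, G=0.7 * np.eye(2),
                               R=0.3 * np.eye(2), tpcs_per_species=4)
        d = build_design(df, pc, response_cols=names)
        spec = ModelSpec(n_chains=2, n_iter=16000, burn_in=2000, thin=5,
                         seed=9)
        _, summary = run_model(d, spec)
        assert max(summary.psrf.values()) < 1.1
        assert min(summary.ess.values()) > 200
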