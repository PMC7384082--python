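"""Ground-truth generators: trees, traits, curves, trajectories."""

import numpy as np
import pytest

from tpcevo.phylo import phylo_covariance
from tpcevo.synthetic_data import (
    apply_missingness,
    back_transform_to_tpc,
    consistent_trait_vector,
    draw_tpc_params,
    simulate_growth_curves,
    simulate_traits,
    simulate_trajectories,
    simulate_tree,
    substream,
)
from tpcevo.trait_transforms import back_transform_values, transform_values


class TestTree:
    def test_two_taxa_unit_depth(self):
        tree = simulate_tree(2, seed=0)
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        depths = [l.root_distance for l in tree.leaf_node_iter()]
        assert depths == pytest.approx([1.0, 1.0])

    def test_same_seed_same_newick(self):
        a = simulate_tree(12, seed=4).as_string(schema="newick")
        b = simulate_tree(12, seed=4).as_string(schema="newick")
        assert a == b

    def test_ultrametric_by_path_sums(self):
        tree = simulate_tree(50, seed=8)
        # brute-force root-to-tip path sums
        depths = []
        for leaf in tree.leaf_node_iter():
            d, nd = 0.0, leaf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            depths.append(d)
        assert np.var(depths) < 1e-24
        assert max(depths) == pytest.approx(1.0)


class TestTraits:
    def test_null_phylogeny_gives_unstructured_traits(self):
        tree = simulate_tree(80, seed=2)
        pc = phylo_covariance(tree)
        df, _ = simulate_traits(pc, np.zeros((1, 1)), np.eye(1),
                                tpcs_per_species=1, seed=3,
                                response_names=["x"])
        v = df.set_index("taxon_id").loc[list(pc.taxa), "x"].to_numpy()
        # Mantel-style check: trait distance uncorrelated with relatedness
        iu = np.triu_indices(pc.n, 1)
        trait_dist = np.abs(v[:, None] - v[None, :])[iu]
        r = np.corrcoef(trait_dist, pc.A[iu])[0, 1]
        assert abs(r) < 0.1

    def test_latitude_slope_recovered_by_ols(self):
        tree = simulate_tree(80, seed=4)
        pc = phylo_covariance(tree)
        beta = np.array([[0.0], [0.5]])
        df, truth = simulate_traits(pc, 0.05 * np.eye(1), 0.2 * np.eye(1),
                                    beta=beta, latitude_slope_design=True,
                                    tpcs_per_species=1, seed=5,
                                    response_names=["x"])
        z = truth["z_abs_latitude"]
        slope = np.polyfit(z, df["x"].to_numpy(), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.15)

    def test_missingness_mask(self):
        tree = simulate_tree(30, seed=6)
        pc = phylo_covariance(tree)
        df, _ = simulate_traits(pc, np.eye(2), np.eye(2),
                                tpcs_per_species=2, seed=7,
                                response_names=["a", "b"])
        masked, idx = apply_missingness(df, "b", 0.2, seed=1)
        assert masked["b"].isna().sum() == len(idx) == round(0.2 * len(df))
        assert not masked["a"].isna().any()


class TestBackTransform:
    def test_round_trip_identity(self):
        params, _ = draw_tpc_params(5, seed=1)
        for p in params:
            fwd = transform_values(p.b0, p.e_act, p.t_pk, 1.0, p.e_d, 1.0)
            core = fwd[[0, 1, 2, 4]]
            q = back_transform_to_tpc(core, p.t_ref)
            assert q.b0 == pytest.approx(p.b0, rel=1e-12)
            assert q.e_act == pytest.approx(p.e_act, rel=1e-12)
            assert q.t_pk == pytest.approx(p.t_pk, rel=1e-12)
            assert q.e_d == pytest.approx(p.e_d, rel=1e-12)

    def test_ed_below_e_rejected(self):
        core = np.array([0.05, np.log(0.8), 293.0 ** 2, np.log(0.7)])
        with pytest.raises(ValueError, match="ED"):
            back_transform_to_tpc(core)

    def test_rejection_count_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        mean = np.array([0.05, np.log(0.65), 293.0 ** 2, np.log(0.9)])
        cov = np.diag([1e-4, 0.09, 8e6, 0.5])
        params, n_rej = draw_tpc_params(
            200, seed=9, mean_core=mean, cov_core=cov,
            max_reject_fraction=0.999)
        # brute-force re-evaluation of the constraint on the same stream
        rng2 = np.random.default_rng(9)
        n_rej2 = 0
        n_ok = 0
        while n_ok < 200:
            d = rng2.multivariate_normal(mean, cov)
            e, ed = np.exp(d[1]), np.exp(d[3])
            tpk = np.sqrt(d[2]) if d[2] > 0 else -1
            if d[0] <= 0 or ed <= e + 1e-3 or not 255 <= tpk <= 330:
                n_rej2 += 1
            else:
                n_ok += 1
        assert n_rej == n_rej2

    def test_consistent_vector_matches_curve(self):
        params, _ = draw_tpc_params(3, seed=11)
        for p in params:
            v = consistent_trait_vector(p)
            back = back_transform_values(v)
            assert back[1] == pytest.approx(p.e_act, rel=1e-10)
            assert back[3] >= back[0]  # Bpk >= B(Tref)


class TestGrowthCurves:
    def test_noise_free_on_curve(self):
        from tpcevo.tpc_core import TPCParams, evaluate_tpc

        p = TPCParams(b0=1e-5, e_act=0.6, t_pk=292.0, e_d=2.4, t_ref=273.15)
        s = simulate_growth_curves(p, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(s.rates, evaluate_tpc(p, s.temperatures))

    def test_rise_only_stays_below_peak(self):
        from tpcevo.tpc_core import TPCParams

        p = TPCParams(b0=1e-5, e_act=0.6, t_pk=292.0, e_d=2.4, t_ref=273.15)
        s = simulate_growth_curves(p, plan="rise_only", seed=1)
        assert np.all(s.temperatures < p.t_pk)

    def test_noise_reproducible(self):
        from tpcevo.tpc_core import TPCParams

        p = TPCParams(b0=1e-5, e_act=0.6, t_pk=292.0, e_d=2.4, t_ref=273.15)
        a = simulate_growth_curves(p, noise_sd=0.05, seed=2)
        b = simulate_growth_curves(p, noise_sd=0.05, seed=2)
        np.testing.assert_array_equal(a.rates, b.rates)


class TestTrajectories:
    def test_zero_variance_walk_constant(self):
        from tpcevo.env_summaries import summarize_trajectories

        traj = simulate_trajectories(3, 100, seed=0, t_sd=0.0, lat_sd=0.0)
        s = summarize_trajectories(traj, 50)[0]
        assert s.t_iqr == 0.0 and s.lat_iqr == 0.0

    def test_same_seed_identical_tables(self):
        a = simulate_trajectories(4, 60, seed=5)
        b = simulate_trajectories(4, 60, seed=5)
        assert a.equals(b)

    def test_ar1_lag_one_autocorrelation(self):
        traj = simulate_trajectories(100, 400, seed=6, rho=0.95, t_sd=1.0)
        rs = []
        for _, g in traj.groupby("replicate_id"):
            x = g.sort_values("day")["temperature_C"].to_numpy()
            rs.append(np.corrcoef(x[:-1], x[1:])[0, 1])
        assert np.mean(rs) == pytest.approx(0.95, abs=0.05)


def test_substreams_are_independent_and_reproducible():
    a1 = substream(7, "fit").standard_normal(5)
    a2 = substream(7, "fit").standard_normal(5)
    b = substream(7, "traits").standard_normal(5)
    np.testing.assert_array_equal(a1, a2)
    assert not np.allclose(a1, b)
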