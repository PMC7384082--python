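"""Ground-truth simulators for every stage of the pipeline.

Generates pure-birth trees, multivariate trait data with known
heritable (G) and residual (R) covariance evolving on the tree, noisy
unimodal growth curves (including nonpositive rates and truncated
temperature coverage, so the preprocessing and missingness machinery
has real work to do), and AR(1) drift trajectories.  All randomness
flows from a single master seed through named substreams so each
stage is independently reproducible.

Default parameter ranges reflect typical phytoplankton growth TPCs:
activation energy lognormal around 0.65 eV, peak temperatures around
293 K (sd 5 K), deactivation energy 3-6x the activation energy, and
baseline rates around 5e-6 s^-1 (about 0.4 per day).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from tpcevo.phylo import PhyloCovariance, phylo_covariance
from tpcevo.tpc_core import TPCParams, compute_bpk, derive_tpc, evaluate_tpc
from tpcevo.trait_transforms import TRAIT_NAMES, transform_values

logger = logging.getLogger(__name__)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG substream named after its stage."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, tag])


@dataclass
class SimulationConfig:
    """Study conditions for an end-to-end simulation.

    The TPC-per-species distribution mirrors the composition of real
    compilations: most species contribute a single curve, about a
    third contribute two to five, and a few contribute up to twelve.
    """

    n_taxa: int = 60
    master_seed: int = 0
    G_true: np.ndarray | None = None
    R_true: np.ndarray | None = None
    beta_true: np.ndarray | None = None
    noise_sd: float = 0.05           # fraction of Bpk, additive
    temperature_points: int = 10
    tpcs_per_species: tuple = ((1, 0.56), (2, 0.12), (3, 0.10), (4, 0.08),
                               (5, 0.07), (8, 0.04), (12, 0.03))
    missing_fraction: float = 0.0
    t_ref: float = 273.15


# ---------------------------------------------------------------------------
# trees


def simulate_tree(n_taxa: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree on ``n_taxa`` tips, scaled to unit height.

    Tips are labelled ``t1 .. tN``.  Identical seeds give identical
    Newick strings.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    # grow a Yule tree: start with 2 lineages at the root, split a random
    # lineage at exponential waiting times until n_taxa lineages exist;
    # ultrametric by construction (all tips extended to the final time)
    tree = dendropy.Tree()
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        child._birth = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        victim = active[int(rng.integers(len(active)))]
        victim.edge.length = t - victim._birth
        active.remove(victim)
        for _ in range(2):
            child = dendropy.Node()
            victim.add_child(child)
            child._birth = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    for nd in active:
        nd.edge.length = t_end - nd._birth
    # label tips deterministically
    ns = tree.taxon_namespace
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        tx = ns.new_taxon(label=f"t{i}")
        leaf.taxon = tx
    # scale to unit height
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(l.root_distance for l in tree.leaf_node_iter())
    if height > 0:
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length /= height
    return tree


# ---------------------------------------------------------------------------
# traits on the tree


def _draw_counts(n_taxa: int, dist, rng) -> np.ndarray:
    vals = np.array([v for v, _ in dist])
    probs = np.array([p for _, p in dist], dtype=float)
    probs /= probs.sum()
    return rng.choice(vals, size=n_taxa, p=probs)


def simulate_traits(
    phylo: PhyloCovariance,
    G: np.ndarray,
    R: np.ndarray,
    beta: np.ndarray | None = None,
    response_names=None,
    tpcs_per_species=1,
    latitude_slope_design: bool = False,
    n_null_covariates: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Multivariate traits evolving on a tree with known G and R.

    Species effects are matrix-normal with covariance ``G (x) A``;
    each TPC observation adds residual noise with covariance ``R``.
    ``beta`` (p x k) supplies fixed effects: row 0 is the per-response
    intercept and, when ``latitude_slope_design`` is set, row 1
    multiplies the standardized absolute latitude of the species'
    (synthetic) isolation location.  Returns the observation table and
    a truth dictionary (species effects, per-observation expectations)
    for recovery scoring.
    """
    rng = np.random.default_rng(seed)
    A = phylo.A
    m = A.shape[0]
    G = np.atleast_2d(np.asarray(G, float))
    R = np.atleast_2d(np.asarray(R, float))
    k = G.shape[0]
    if response_names is None:
        response_names = [f"trait_{j}" for j in range(k)]
    if np.isscalar(tpcs_per_species):
        counts = np.full(m, int(tpcs_per_species))
    else:
        counts = _draw_counts(m, tpcs_per_species, rng)
    n = int(counts.sum())
    sp_idx = np.repeat(np.arange(m), counts)

    latitude = rng.uniform(-70, 70, size=m)
    habitat = rng.choice(["marine", "freshwater"], size=m)
    lat_obs = latitude[sp_idx]
    abs_lat = np.abs(lat_obs)
    z_lat = (abs_lat - abs_lat.mean()) / (abs_lat.std() or 1.0)

    p = 1 + int(latitude_slope_design)
    if beta is None:
        beta = np.zeros((p, k))
    beta = np.atleast_2d(np.asarray(beta, float))
    X = np.ones((n, 1)) if p == 1 else np.column_stack([np.ones(n), z_lat])

    # species effects: U = L_A Z L_G', so vec(U) ~ N(0, G (x) A)
    def _chol(Mt, label):
        w, V = np.linalg.eigh(Mt)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)

    L_A = _chol(A, "A")
    L_G = _chol(G, "G")
    L_R = _chol(R, "R")
    U = L_A @ rng.standard_normal((m, k)) @ L_G.T
    E = rng.standard_normal((n, k)) @ L_R.T
    mu = X @ beta[:p]
    Yt = mu + U[sp_idx] + E

    df = pd.DataFrame(Yt, columns=list(response_names))
    df.insert(0, "taxon_id", [phylo.taxa[s] for s in sp_idx])
    df["latitude"] = lat_obs
    df["habitat"] = habitat[sp_idx]
    for c in range(n_null_covariates):
        df[f"null_cov_{c}"] = rng.standard_normal(n)
    truth = {"U": U, "mu": mu, "Y_true": Yt, "beta": beta[:p],
             "species_idx": sp_idx, "latitude": latitude,
             "z_abs_latitude": z_lat}
    return df, truth


def add_measurement_error(df: pd.DataFrame, response_names, sd,
                          seed: int = 0) -> pd.DataFrame:
    """Add known Gaussian measurement error and matching variance columns."""
    rng = np.random.default_rng(seed)
    out = df.copy()
    sds = np.broadcast_to(np.asarray(sd, float), (len(response_names),))
    for j, c in enumerate(response_names):
        out[c] = out[c] + rng.normal(0.0, sds[j], size=len(out))
        out[f"{c}_var"] = sds[j] ** 2
    return out


def apply_missingness(df: pd.DataFrame, column: str, fraction: float,
                      seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Mask a random fraction of one column (missing completely at
    random); returns the masked frame and the masked row indices."""
    rng = np.random.default_rng(seed)
    out = df.copy()
    n_mask = int(round(fraction * len(out)))
    idx = rng.choice(len(out), size=n_mask, replace=False)
    out.iloc[idx, out.columns.get_loc(column)] = np.nan
    return out, np.sort(idx)


# ---------------------------------------------------------------------------
# TPC parameter draws and growth curves


def back_transform_to_tpc(core_values, t_ref: float = 273.15) -> TPCParams:
    """Invert the core-trait transforms to a parameter set.

    ``core_values`` is ``(B0^1/4, ln E, Tpk^2, ln ED)``.  Raises
    ``ValueError`` when the draw violates ``ED > E + 1e-3`` or has a
    nonpositive squared peak temperature; callers drawing from a
    multivariate normal should reject and redraw.
    """
    v = np.asarray(core_values, float)
    b0 = v[0] ** 4
    e = float(np.exp(v[1]))
    if v[2] <= 0:
        raise ValueError("nonpositive Tpk^2 draw")
    t_pk = float(np.sqrt(v[2]))
    e_d = float(np.exp(v[3]))
    if e_d <= e + 1e-3:
        raise ValueError("ED must exceed E by more than 1e-3 eV")
    return TPCParams(b0=b0, e_act=e, t_pk=t_pk, e_d=e_d, t_ref=t_ref)


def default_core_means(t_ref: float = 273.15) -> np.ndarray:
    """Realistic central values on the transformed core-trait scale."""
    return np.array([
        (5e-6) ** 0.25,        # B0^(1/4), B0 ~ 5e-6 s^-1
        np.log(0.65),          # ln E
        293.0 ** 2,            # Tpk^2
        np.log(4 * 0.65),      # ln ED ~ 4x E
    ])


def draw_tpc_params(
    n: int,
    seed: int = 0,
    t_ref: float = 273.15,
    mean_core: np.ndarray | None = None,
    cov_core: np.ndarray | None = None,
    tpk_bounds: tuple = (255.0, 330.0),
    max_reject_fraction: float = 0.5,
) -> tuple[list, int]:
    """Draw internally consistent parameter sets from a trait normal.

    Draws core trait vectors from a multivariate normal, rejects any
    violating ``ED > E + 1e-3`` or the peak-temperature bounds, and
    redraws until ``n`` valid sets exist.  Returns ``(params_list,
    n_rejected)``; an overall rejection rate above 50% raises with
    advice to revisit the parameter ranges.
    """
    rng = np.random.default_rng(seed)
    if mean_core is None:
        mean_core = default_core_means(t_ref)
    if cov_core is None:
        cov_core = np.diag([
            (0.15 * mean_core[0]) ** 2,
            0.3 ** 2,                       # sd of ln E
            (2 * 293.0 * 5.0) ** 2,         # Tpk sd ~ 5 K on the sq scale
            0.25 ** 2,                      # sd of ln ED
        ])
    out: list[TPCParams] = []
    n_reject = 0
    n_drawn = 0
    while len(out) < n:
        draw = rng.multivariate_normal(mean_core, cov_core)
        n_drawn += 1
        try:
            p = back_transform_to_tpc(draw, t_ref)
            if not tpk_bounds[0] <= p.t_pk <= tpk_bounds[1]:
                raise ValueError("Tpk outside bounds")
            out.append(p)
        except ValueError:
            n_reject += 1
            if n_drawn >= 20 and n_reject / n_drawn > max_reject_fraction:
                raise RuntimeError(
                    "rejection rate above 50%; widen ED relative to E or "
                    "narrow the Tpk spread in the generating distribution")
    if n_reject:
        logger.info("draw_tpc_params: %d draws rejected", n_reject)
    return out, n_reject


def consistent_trait_vector(params: TPCParams) -> np.ndarray:
    """Six transformed traits derived from one parameter set via the
    curve itself, so Bpk and Wop are internally consistent."""
    d = derive_tpc(params)
    return transform_values(d.b_at_ref, params.e_act, params.t_pk,
                            d.b_pk, params.e_d, d.w_op)


COVERAGE_PLANS = ("full", "rise_only", "sparse")


def simulate_growth_curves(
    params: TPCParams,
    temp_grid: np.ndarray | None = None,
    noise_sd: float = 0.05,
    plan: str = "full",
    n_points: int = 10,
    seed: int = 0,
    taxon_id: str = "sim",
):
    """Noisy growth-rate measurements from a known curve.

    Rates are ``B(T) + N(0, noise_sd * Bpk)`` -- additive noise, so
    nonpositive rates occur naturally in the cold tail and exercise
    the preprocessing removal rule.  Coverage plans: ``full`` spans
    the peak, ``rise_only`` stops at the peak (so fall-side parameters
    are unidentifiable, exercising the missing-at-random flags), and
    ``sparse`` uses five points.
    """
    from tpcevo.tpc_fit import GrowthRateSeries

    if plan not in COVERAGE_PLANS:
        raise ValueError(f"plan must be one of {COVERAGE_PLANS}")
    rng = np.random.default_rng(seed)
    tpk = params.t_pk
    if temp_grid is None:
        if plan == "full":
            temp_grid = np.linspace(tpk - 20.0, tpk + 8.0, n_points)
        elif plan == "rise_only":
            temp_grid = np.linspace(tpk - 20.0, tpk - 0.5, n_points)
        else:
            temp_grid = np.linspace(tpk - 18.0, tpk + 6.0, 5)
    temp_grid = np.asarray(temp_grid, float)
    clean = evaluate_tpc(params, temp_grid)
    sd = noise_sd * compute_bpk(params)
    rates = clean + rng.normal(0.0, sd, size=temp_grid.size) if sd > 0 else clean.copy()
    return GrowthRateSeries(taxon_id=taxon_id, temperatures=temp_grid,
                            rates=rates)


# ---------------------------------------------------------------------------
# drift trajectories


def simulate_trajectories(
    n_replicates: int,
    n_days: int,
    seed: int = 0,
    location_id: str = "loc1",
    depth_m: float = 50.0,
    t_mean: float = 15.0,
    lat_mean: float = 30.0,
    rho: float = 0.95,
    t_sd: float = 0.5,
    lat_sd: float = 0.2,
    lengths: np.ndarray | None = None,
) -> pd.DataFrame:
    """AR(1) temperature and latitude walks in the trajectory schema.

    Each replicate is a stationary AR(1) process around its mean with
    lag-1 autocorrelation ``rho`` and innovation scale chosen so the
    marginal standard deviations are ``t_sd`` and ``lat_sd``.
    ``lengths`` optionally shortens individual replicates (default:
    all run ``n_days``).
    """
    if n_days > 500:
        raise ValueError("n_days must be <= 500")
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = np.full(n_replicates, n_days, dtype=int)
    rows = []
    innov_t = t_sd * np.sqrt(1 - rho ** 2)
    innov_l = lat_sd * np.sqrt(1 - rho ** 2)
    for rep in range(n_replicates):
        L = int(lengths[rep])
        t = t_mean + t_sd * rng.standard_normal()
        lat = lat_mean + lat_sd * rng.standard_normal()
        for day in range(1, L + 1):
            rows.append((location_id, depth_m, f"rep{rep + 1}", day, t, lat))
            t = t_mean + rho * (t - t_mean) + innov_t * rng.standard_normal()
            lat = lat_mean + rho * (lat - lat_mean) + innov_l * rng.standard_normal()
    return pd.DataFrame(rows, columns=["location_id", "depth_m",
                                       "replicate_id", "day",
                                       "temperature_C", "latitude_deg"])


def tree_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Convenience: relatedness matrix of a simulated tree."""
    return phylo_covariance(tree)
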