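"""Multi-response phylogenetic mixed model ("animal model") by Gibbs sampling.

Each observation (one fitted TPC) carries a k-vector of transformed
traits.  The model is

    y_i = B' x_i + u_{s(i)} + e_i,        e_i ~ N(0, R)
    vec(U) ~ N(0, G (x) A)                (species effects)
    w_ij = y_ij + m_ij,  m_ij ~ N(0, v_ij)  (known measurement error)

where ``A`` is the phylogenetic relatedness matrix, ``G`` the
phylogenetically heritable trait covariance, ``R`` the residual
covariance, and ``B`` holds a distinct coefficient per (covariate,
response) pair.  Missing responses are treated as missing at random
and imputed inside the sampler.  All full conditionals are conjugate
(normal for B, U and the latent y; inverse-Wishart for G and R), so
the sampler is a blocked Gibbs scheme.

Diagnostics follow common MCMC practice: the Gelman--Rubin potential
scale reduction factor across chains, autocorrelation-time effective
sample sizes on merged chains, and DIC (mean deviance plus the
effective parameter count pD) with the deviance conditional on the
species effects, as in MCMCglmm.  Phylogenetic heritability
``G_ii / (G_ii + R_ii)`` is equivalent to Pagel's lambda in this model
class; measurement-error variance is excluded from the denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.stats import invgamma

from tpcevo.phylo import PhyloCovariance
from tpcevo.trait_transforms import TRAIT_NAMES

logger = logging.getLogger(__name__)

FIXED_EFFECT_CHOICES = (
    "intercepts_only",
    "abs_latitude",
    "latitude_poly2",
    "habitat",
    "latitude_plus_habitat",
)


@dataclass
class ModelSpec:
    """Configuration for one candidate model.

    ``fixed_effects`` is one of :data:`FIXED_EFFECT_CHOICES` or a list
    of covariate column names (used for the marine thermal-regime
    variants).  Chain defaults are scaled for desk-size problems; the
    prior is inverse-Wishart with ``Psi = psi_scale * I`` and ``nu =
    k - 1 + nu_extra``, whose marginal on each variance is exactly the
    weakly informative inverse-gamma(0.001, 0.001).
    """

    fixed_effects: object = "intercepts_only"
    n_chains: int = 2
    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    psi_scale: float = 0.002
    nu_extra: float = 0.002

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")


@dataclass
class Design:
    """Assembled model inputs: responses, error variances, fixed design."""

    Y: np.ndarray                 # n x k, NaN = missing
    V: np.ndarray                 # n x k known measurement-error variances
    X: np.ndarray                 # n x p
    col_names: list
    col_groups: dict              # fixed-effect name -> list of column idx
    species_idx: np.ndarray       # n, index into phylo.taxa
    phylo: PhyloCovariance
    response_names: tuple
    standardization: dict = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def k(self) -> int:
        return self.Y.shape[1]


@dataclass
class ChainSamples:
    """Stored draws from one chain."""

    beta: np.ndarray              # S x p x k
    G: np.ndarray                 # S x k x k
    R: np.ndarray                 # S x k x k
    U: np.ndarray                 # S x m x k
    y_missing: np.ndarray         # S x n_missing
    missing_where: np.ndarray     # n_missing x 2 (row, col)
    deviance: np.ndarray          # S
    dic: float = np.nan
    p_d: float = np.nan


@dataclass
class PosteriorSamples:
    """Draws from all chains of one fitted model."""

    chains: list
    design: Design
    spec: ModelSpec

    def merged(self, attr: str) -> np.ndarray:
        return np.concatenate([getattr(c, attr) for c in self.chains])


@dataclass
class ModelSummary:
    """Diagnostics and posterior summaries for one candidate model."""

    name: str
    dic: float
    dic_per_chain: list
    psrf: dict
    ess: dict
    beta_mean: dict               # (covariate, response) -> mean
    beta_hpd: dict                # (covariate, response) -> (lo, hi)
    col_groups: dict
    col_names: list
    response_names: tuple
    n_fixed_columns: int
    heritability: dict | None = None
    correlations: dict | None = None


# ---------------------------------------------------------------------------
# design construction


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu, sd = float(np.mean(x)), float(np.std(x))
    if sd == 0:
        sd = 1.0
    return (x - mu) / sd, mu, sd


def build_design(
    df: pd.DataFrame,
    phylo: PhyloCovariance,
    fixed_effects: object = "intercepts_only",
    response_cols=TRAIT_NAMES,
    var_cols=None,
) -> Design:
    """Assemble the stacked multi-response design.

    ``df`` must carry one row per TPC with a ``taxon_id`` column whose
    values are tips of the (pruned) tree, one column per response, and
    optionally per-response measurement-error variance columns
    (``var_cols``, NaN or absent meaning zero/unknown) plus whatever
    covariates the fixed-effect structure needs (``latitude``,
    ``habitat``, or named columns).  Observations missing a needed
    covariate are dropped with a log entry.  Continuous covariates are
    centered and scaled (recorded for back-transforming coefficients).
    """
    df = df.copy()
    tip_index = {t: i for i, t in enumerate(phylo.taxa)}
    bad = set(df["taxon_id"]) - set(tip_index)
    if bad:
        raise KeyError(f"taxa not in tree: {sorted(bad)}")

    needed: list[str] = []
    if isinstance(fixed_effects, str):
        if fixed_effects not in FIXED_EFFECT_CHOICES:
            raise ValueError(f"unknown fixed_effects {fixed_effects!r}")
        if "latitude" in fixed_effects:
            needed.append("latitude")
        if "habitat" in fixed_effects:
            needed.append("habitat")
    else:
        needed = list(fixed_effects)

    n0 = len(df)
    for c in needed:
        df = df[df[c].notna()]
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("build_design: dropped %d observations missing %s",
                    n_dropped, needed)

    n = len(df)
    std: dict = {}
    cols = [np.ones(n)]
    names = ["intercept"]
    groups: dict = {}

    def add(name: str, values: np.ndarray, group: str,
            scale: bool = True) -> None:
        if scale:
            z, mu, sd = _standardize(values)
            std[name] = (mu, sd)
        else:
            z = values
        groups.setdefault(group, []).append(len(cols))
        cols.append(z)
        names.append(name)

    if fixed_effects == "abs_latitude":
        add("abs_latitude", np.abs(df["latitude"].to_numpy(float)), "latitude")
    elif fixed_effects == "latitude_poly2":
        z, mu, sd = _standardize(df["latitude"].to_numpy(float))
        std["latitude"] = (mu, sd)
        add("latitude", z, "latitude", scale=False)
        add("latitude_sq", z ** 2, "latitude", scale=False)
    elif fixed_effects == "habitat":
        add("habitat_marine",
            (df["habitat"].astype(str) == "marine").to_numpy(float),
            "habitat", scale=False)
    elif fixed_effects == "latitude_plus_habitat":
        add("abs_latitude", np.abs(df["latitude"].to_numpy(float)), "latitude")
        add("habitat_marine",
            (df["habitat"].astype(str) == "marine").to_numpy(float),
            "habitat", scale=False)
    elif isinstance(fixed_effects, (list, tuple)):
        for c in fixed_effects:
            add(c, df[c].to_numpy(float), c)

    X = np.column_stack(cols)
    Y = df[list(response_cols)].to_numpy(float)
    if var_cols is not None:
        V = df[list(var_cols)].to_numpy(float)
        V = np.where(np.isfinite(V), V, 0.0)
        V = np.maximum(V, 0.0)
    else:
        V = np.zeros_like(Y)
    V[np.isnan(Y)] = 0.0
    sp = df["taxon_id"].map(tip_index).to_numpy(int)
    return Design(Y=Y, V=V, X=X, col_names=names, col_groups=groups,
                  species_idx=sp, phylo=phylo,
                  response_names=tuple(response_cols),
                  standardization=std, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# numerics helpers


def _chol_psd(M: np.ndarray, what: str):
    """Lower Cholesky with a single jittered retry, then a hard abort."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * (1.0 + np.trace(M) / M.shape[0])
        try:
            L = np.linalg.cholesky(M + jitter * np.eye(M.shape[0]))
            logger.warning("non-PD %s conditional; recovered with jitter", what)
            return L
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                f"non-PD {what} conditional even after jitter; "
                f"diag={np.diag(M)}") from exc


def _kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Kronecker product via broadcasting (faster than np.kron here)."""
    ra, ca = a.shape
    rb, cb = b.shape
    return (a[:, None, :, None] * b[None, :, None, :]).reshape(ra * rb, ca * cb)


def _invwishart_rvs(df: float, scale: np.ndarray, rng) -> np.ndarray:
    """One inverse-Wishart draw by Bartlett decomposition.

    Sample W ~ Wishart(df, scale^-1) as T T' with T = chol(scale^-1) A,
    A lower-triangular with chi-distributed diagonal; return W^-1.
    """
    k = scale.shape[0]
    L_inv = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((k, k))
    for i in range(k):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
    idx = np.tril_indices(k, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    T = L_inv @ A
    T_inv = solve_triangular(T, np.eye(k), lower=True)
    return T_inv.T @ T_inv


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(draws, float))
    n = x.size
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


# ---------------------------------------------------------------------------
# the Gibbs sampler


def _row_patterns(Y: np.ndarray, V: np.ndarray):
    """Group rows by their (fixed, free, noisy) entry pattern.

    "fixed" entries are observed with zero error variance (the latent
    value equals the datum); "free" entries are missing or noisy and
    must be sampled.  Rows that are entirely fixed are skipped by the
    latent update.
    """
    n, k = Y.shape
    obs = np.isfinite(Y)
    noisy = obs & (V > 0)
    fixed = obs & (V == 0)
    patterns: dict = {}
    for i in range(n):
        key = (tuple(np.flatnonzero(fixed[i])), tuple(np.flatnonzero(noisy[i])),
               tuple(np.flatnonzero(~obs[i])))
        patterns.setdefault(key, []).append(i)
    out = []
    for (fx, ny, ms), rows in patterns.items():
        free = tuple(sorted(ny + ms))
        if not free:
            continue
        out.append((np.array(fx, int), np.array(free, int),
                    np.array(ny, int), np.array(ms, int), np.array(rows, int)))
    return out


def gibbs_sample(
    design: Design,
    n_iter: int,
    burn_in: int,
    thin: int = 5,
    seed: int = 0,
    psi_scale: float = 0.002,
    nu_extra: float = 0.002,
    fix_g_zero: bool = False,
    interweave: bool = True,
) -> ChainSamples:
    """Run one chain of the blocked Gibbs sampler.

    Update cycle: (1) latent trait values given data and measurement
    error (also imputes missing responses), (2) fixed effects from
    their matrix-normal full conditional, (3) species effects jointly
    using the relatedness inverse and current G, (4) G from its
    inverse-Wishart full conditional, (5) R likewise from the
    residuals.  ``fix_g_zero`` pins the species effects (and G) at
    zero, the degenerate mode used to validate against closed-form
    GLS.  Deviance is recorded per stored draw, conditional on the
    species effects and marginal over the latent values.
    """
    rng = np.random.default_rng(seed)
    Y, V, X = design.Y, design.V, design.X
    n, k = Y.shape
    p = X.shape[1]
    sp = design.species_idx
    A_inv = design.phylo.A_inv
    m = design.phylo.n
    counts = np.bincount(sp, minlength=m).astype(float)
    # IW(nu, Psi) marginal on each diagonal variance is
    # IG((nu-k+1)/2, Psi_ii/2); nu = k-1+0.002, Psi = 0.002 I makes that
    # exactly the weakly informative inverse-gamma(0.001, 0.001)
    nu0 = k - 1 + nu_extra
    Psi0 = psi_scale * np.eye(k)

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX + 1e-12 * np.eye(p))
    L_x = cholesky(XtX_inv, lower=True)

    # intercept column (for the interweaving move); A_inv-weighted ones
    intercept_candidates = [j for j in range(p)
                            if np.all(X[:, j] == 1.0)]
    intercept_col = intercept_candidates[0] if intercept_candidates else None
    w_ones = A_inv @ np.ones(m)
    s_ones = float(np.ones(m) @ w_ones)
    _tri_k = np.tril_indices(k, -1)
    _iw_expo = np.arange(k, 0, -1) + 1      # G->chol Jacobian exponents
    _eye_k = np.eye(k)

    obs_mask = np.isfinite(Y)
    miss_where = np.argwhere(~obs_mask)
    patterns = _row_patterns(Y, V)

    # deviance patterns: rows grouped by observed set; within a group the
    # covariance R_oo + diag(v) is shared only when v matches, so group by
    # (observed set, rounded v) for batching
    dev_groups: dict = {}
    for i in range(n):
        o = tuple(np.flatnonzero(obs_mask[i]))
        key = (o, tuple(np.round(V[i, list(o)], 14)))
        dev_groups.setdefault(key, []).append(i)
    dev_groups = [(np.array(o, int), np.array(v), np.array(rows, int))
                  for (o, v), rows in dev_groups.items()]

    # state
    Ytrue = Y.copy()
    col_means = np.nanmean(np.where(obs_mask, Y, np.nan), axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    for i, j in miss_where:
        Ytrue[i, j] = col_means[j]
    beta = np.linalg.lstsq(X, Ytrue, rcond=None)[0]
    U = np.zeros((m, k))
    resid0 = Ytrue - X @ beta
    R = np.diag(np.maximum(np.var(resid0, axis=0), 1e-8))
    G = 0.5 * R.copy() if not fix_g_zero else np.zeros((k, k))

    n_store = (n_iter - burn_in) // thin
    S_beta = np.empty((n_store, p, k))
    S_G = np.empty((n_store, k, k))
    S_R = np.empty((n_store, k, k))
    S_U = np.empty((n_store, m, k))
    S_ymiss = np.empty((n_store, len(miss_where)))
    S_dev = np.empty(n_store)

    def deviance(beta_, U_, R_) -> float:
        mu = X @ beta_ + U_[sp]
        dev = 0.0
        for o, v, rows in dev_groups:
            if o.size == 0:
                continue
            Sg = R_[np.ix_(o, o)] + np.diag(v)
            Ls = _chol_psd(Sg, "deviance")
            resid = (Y[np.ix_(rows, o)] - mu[np.ix_(rows, o)]).T
            z = solve_triangular(Ls, resid, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(Ls)))
            dev += rows.size * (o.size * np.log(2 * np.pi) + logdet)
            dev += float(np.sum(z ** 2))
        return dev

    stored = 0
    for it in range(n_iter):
        mu = X @ beta + U[sp]

        # (1) latent trait values / MAR imputation
        if patterns:
            Rinv_full = np.linalg.inv(R)
            for fx, free, ny, ms, rows in patterns:
                kf = free.size
                if fx.size:
                    R_ff = R[np.ix_(fx, fx)]
                    R_qf = R[np.ix_(free, fx)]
                    gain = R_qf @ np.linalg.inv(R_ff)
                    C = R[np.ix_(free, free)] - gain @ R_qf.T
                else:
                    gain = None
                    C = R[np.ix_(free, free)]
                C_inv = np.linalg.inv(_symmetrize(C))
                for i in rows:
                    m_c = mu[i, free]
                    if gain is not None:
                        m_c = m_c + gain @ (Y[i, fx] - mu[i, fx])
                    P = C_inv.copy()
                    b = C_inv @ m_c
                    if ny.size:
                        loc = np.searchsorted(free, ny)
                        w = 1.0 / V[i, ny]
                        P[loc, loc] += w
                        b[loc] += w * Y[i, ny]
                    Lp = _chol_psd(P, "latent")
                    mean = cho_solve((Lp, True), b)
                    draw = mean + solve_triangular(
                        Lp.T, rng.standard_normal(kf), lower=False)
                    Ytrue[i, free] = draw

        # (2) fixed effects
        Yr = Ytrue - U[sp]
        beta_hat = XtX_inv @ (X.T @ Yr)
        L_R = _chol_psd(R, "R")
        beta = beta_hat + L_x @ rng.standard_normal((p, k)) @ L_R.T

        # (3) species effects
        if not fix_g_zero:
            E = Ytrue - X @ beta
            S_sum = np.zeros((m, k))
            np.add.at(S_sum, sp, E)
            Rinv = np.linalg.inv(R)
            Ginv = np.linalg.inv(G)
            P = _kron(Ginv, A_inv) + _kron(Rinv, np.diag(counts))
            b = (S_sum @ Rinv).flatten(order="F")
            Lp = _chol_psd(_symmetrize(P), "species-effect")
            mean = cho_solve((Lp, True), b)
            draw = mean + solve_triangular(
                Lp.T, rng.standard_normal(m * k), lower=False)
            U = draw.reshape((m, k), order="F")

            # interweaving (ASIS) move: the likelihood is invariant under
            # shifting all species effects by c and the per-response
            # intercept by -c, so resample that shift from the species-
            # effect prior; this decorrelates the intercept from mean(U)
            if interweave and intercept_col is not None:
                c_mean = (U.T @ w_ones) / s_ones
                L_G = _chol_psd(G, "G")
                c = c_mean + (L_G @ rng.standard_normal(k)) / np.sqrt(s_ones)
                U = U - c[None, :]
                beta[intercept_col] += c

            # (4) heritable covariance
            Sg = U.T @ A_inv @ U
            G = _symmetrize(_invwishart_rvs(nu0 + m, Psi0 + _symmetrize(Sg), rng))

            # scale interweaving: Metropolis update of chol(G) holding the
            # whitened species effects fixed (U moves with G).  The plain
            # conditional G | U mixes very slowly along the correlation
            # directions because most of the A^-1 weight sits on short
            # branches the data cannot resolve; this joint move gives the
            # likelihood a direct say in G.
            if interweave:
                L_G = _chol_psd(G, "G")
                Ut = solve_triangular(L_G, U.T, lower=True)   # whitened
                E_base = Ytrue - X @ beta

                def _move_logdens(L):
                    diag = np.diag(L)
                    if np.any(diag <= 0):
                        return -np.inf
                    Un = (L @ Ut).T
                    Em = E_base - Un[sp]
                    ll = -0.5 * float(((Em @ Rinv) * Em).sum())
                    ld = 2.0 * float(np.log(diag).sum())
                    Linv = solve_triangular(L, _eye_k, lower=True)
                    tr = psi_scale * float((Linv * Linv).sum())
                    lprior = -(nu0 + k + 1) / 2.0 * ld - 0.5 * tr
                    ljac = float(np.sum(_iw_expo * np.log(diag)))
                    return ll + lprior + ljac

                L_prop = L_G.copy()
                d = np.diag(L_prop) * np.exp(0.1 * rng.standard_normal(k))
                L_prop[np.diag_indices(k)] = d
                if k > 1:
                    L_prop[_tri_k] += 0.1 * rng.standard_normal(len(_tri_k[0]))
                if np.log(rng.uniform()) < (_move_logdens(L_prop)
                                            - _move_logdens(L_G)):
                    G = _symmetrize(L_prop @ L_prop.T)
                    U = (L_prop @ Ut).T

        # (5) residual covariance
        E2 = Ytrue - X @ beta - U[sp]
        Sr = E2.T @ E2
        R = _symmetrize(_invwishart_rvs(nu0 + n, Psi0 + _symmetrize(Sr), rng))

        if it >= burn_in and (it - burn_in) % thin == 0 and stored < n_store:
            S_beta[stored] = beta
            S_G[stored] = G
            S_R[stored] = R
            S_U[stored] = U
            if len(miss_where):
                S_ymiss[stored] = Ytrue[miss_where[:, 0], miss_where[:, 1]]
            S_dev[stored] = deviance(beta, U, R)
            stored += 1

    chain = ChainSamples(beta=S_beta[:stored], G=S_G[:stored], R=S_R[:stored],
                         U=S_U[:stored], y_missing=S_ymiss[:stored],
                         missing_where=miss_where, deviance=S_dev[:stored])
    dev_at_mean = deviance(chain.beta.mean(0), chain.U.mean(0),
                           _symmetrize(chain.R.mean(0)))
    dic, p_d, _ = compute_dic(chain.deviance, dev_at_mean)
    chain.dic, chain.p_d = dic, p_d
    return chain


def run_model(design: Design, spec: ModelSpec,
              fix_g_zero: bool = False) -> tuple[PosteriorSamples, ModelSummary]:
    """Fit one candidate model with ``spec.n_chains`` chains and summarize."""
    chains = [
        gibbs_sample(design, spec.n_iter, spec.burn_in, spec.thin,
                     seed=spec.seed + 100003 * c,
                     psi_scale=spec.psi_scale, nu_extra=spec.nu_extra,
                     fix_g_zero=fix_g_zero)
        for c in range(spec.n_chains)
    ]
    samples = PosteriorSamples(chains=chains, design=design, spec=spec)
    summary = summarize_model(samples)
    return samples, summary


# ---------------------------------------------------------------------------
# diagnostics


def compute_psrf(chains: np.ndarray) -> float:
    """Gelman--Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_samples); at least two chains are
    required.  Returns sqrt(((n-1)/n W + B/n) / W).
    """
    c = np.asarray(chains, float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    s = c.shape[1]
    W = float(c.var(axis=1, ddof=1).mean())
    B_over_n = float(c.mean(axis=1).var(ddof=1))
    if W == 0:
        return 1.0
    return float(np.sqrt(((s - 1) / s * W + B_over_n) / W))


def compute_ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator.

    Autocorrelations are computed by FFT; consecutive pairs of
    autocorrelations are summed and accumulation stops at the first
    negative pair (Geyer's initial positive sequence).  A constant
    chain yields 0 with a warning.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 10:
        raise ValueError("need >= 10 samples")
    x = x - x.mean()
    var = float(np.mean(x ** 2))
    if var == 0:
        warnings.warn("constant chain: ESS undefined, reporting 0")
        return 0.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(n / tau)


def compute_dic(deviance_draws: np.ndarray,
                dev_at_mean: float) -> tuple[float, float, float]:
    """DIC = mean deviance + pD with pD = mean deviance - D(at means).

    Returns ``(dic, p_d, mean_deviance)``.
    """
    mean_dev = float(np.mean(deviance_draws))
    p_d = mean_dev - float(dev_at_mean)
    return mean_dev + p_d, p_d, mean_dev


# ---------------------------------------------------------------------------
# posterior summaries


def _scalar_streams(chain: ChainSamples, k: int):
    """Yield (name, per-chain 1-D draw array) for every scalar parameter."""
    p = chain.beta.shape[1]
    for a in range(p):
        for j in range(k):
            yield f"beta[{a},{j}]", chain.beta[:, a, j]
    for i in range(k):
        for j in range(i, k):
            yield f"G[{i},{j}]", chain.G[:, i, j]
            yield f"R[{i},{j}]", chain.R[:, i, j]


def summarize_model(samples: PosteriorSamples,
                    name: str | None = None) -> ModelSummary:
    """PSRF, ESS, DIC and coefficient HPDs for one fitted model."""
    design, spec = samples.design, samples.spec
    k = design.k
    psrf: dict = {}
    ess: dict = {}
    streams_per_chain = [dict(_scalar_streams(c, k)) for c in samples.chains]
    for pname in streams_per_chain[0]:
        arrs = [s[pname] for s in streams_per_chain]
        merged = np.concatenate(arrs)
        if len(arrs) >= 2:
            psrf[pname] = compute_psrf(np.stack(arrs))
        if np.var(merged) > 0:
            ess[pname] = compute_ess(merged)

    dic_per_chain = [c.dic for c in samples.chains]
    beta_all = samples.merged("beta")
    beta_mean: dict = {}
    beta_hpd: dict = {}
    for a, cname in enumerate(design.col_names):
        for j, rname in enumerate(design.response_names):
            d = beta_all[:, a, j]
            beta_mean[(cname, rname)] = float(d.mean())
            beta_hpd[(cname, rname)] = hpd_interval(d)
    fe = spec.fixed_effects
    return ModelSummary(
        name=name or (fe if isinstance(fe, str) else "+".join(fe)),
        dic=float(np.mean(dic_per_chain)),
        dic_per_chain=dic_per_chain,
        psrf=psrf, ess=ess,
        beta_mean=beta_mean, beta_hpd=beta_hpd,
        col_groups=design.col_groups,
        col_names=list(design.col_names),
        response_names=design.response_names,
        n_fixed_columns=design.X.shape[1] * k,
    )


def select_model(summaries: list[ModelSummary]) -> ModelSummary:
    """HPD-exclusion rule, then minimum averaged DIC.

    A model is excluded when any of its non-intercept fixed effects
    has a 95% HPD interval containing zero for every single response.
    Among survivors the lowest averaged DIC wins; DIC differences
    below 0.5 are ties broken toward fewer fixed-effect columns.  If
    every model with covariates is excluded, the intercepts-only model
    (no covariate groups) wins by default.
    """
    if not summaries:
        raise ValueError("no candidate models")

    def excluded(s: ModelSummary) -> bool:
        for group, cols in s.col_groups.items():
            group_names = {s.col_names[a] for a in cols}
            all_zero = all(
                lo <= 0.0 <= hi
                for (cn, _rn), (lo, hi) in s.beta_hpd.items()
                if cn in group_names
            )
            if all_zero:
                return True
        return False

    survivors = [s for s in summaries if not s.col_groups or not excluded(s)]
    if not survivors:
        intercept_only = [s for s in summaries if not s.col_groups]
        if intercept_only:
            return intercept_only[0]
        survivors = summaries
    best_dic = min(s.dic for s in survivors)
    tied = [s for s in survivors if s.dic - best_dic < 0.5]
    return min(tied, key=lambda s: (s.n_fixed_columns, s.dic))


def decompose_correlations(samples: PosteriorSamples,
                           pairs=None) -> dict:
    """Heritable, residual and phenotypic correlations per trait pair.

    Per posterior draw, ``r_her = G_ij / sqrt(G_ii G_jj)``, ``r_res``
    likewise from R, and ``r_phe`` from G + R; each is summarized by
    the posterior mean and 95% HPD interval.
    """
    G = samples.merged("G")
    R = samples.merged("R")
    k = G.shape[1]
    if pairs is None:
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    out: dict = {}
    for i, j in pairs:
        r_her = G[:, i, j] / np.sqrt(G[:, i, i] * G[:, j, j])
        r_res = R[:, i, j] / np.sqrt(R[:, i, i] * R[:, j, j])
        num = G[:, i, j] + R[:, i, j]
        den = np.sqrt((G[:, i, i] + R[:, i, i]) * (G[:, j, j] + R[:, j, j]))
        r_phe = num / den
        out[(i, j)] = {
            name: {"mean": float(np.mean(d)), "hpd": hpd_interval(d)}
            for name, d in (("r_her", r_her), ("r_res", r_res),
                            ("r_phe", r_phe))
        }
    return out


def phylogenetic_heritability(samples: PosteriorSamples) -> dict:
    """Per-trait heritability ``G_ii / (G_ii + R_ii)`` (mean and HPD).

    Should be computed from the intercepts-only model: covariates
    absorb residual variance and bias heritability upward, so a
    warning is issued for any other fixed-effect structure.
    Measurement-error variance is excluded from the denominator.
    """
    if samples.spec.fixed_effects != "intercepts_only":
        warnings.warn("heritability is best estimated from the "
                      "intercepts-only model; covariates inflate it")
    G = samples.merged("G")
    R = samples.merged("R")
    out = {}
    for i, name in enumerate(samples.design.response_names):
        h2 = G[:, i, i] / (G[:, i, i] + R[:, i, i])
        out[name] = {"mean": float(np.mean(h2)), "hpd": hpd_interval(h2)}
    return out


# ---------------------------------------------------------------------------
# univariate sampler (shared by the size-scaling module)


def gibbs_univariate(
    y: np.ndarray,
    X: np.ndarray,
    species_idx: np.ndarray,
    A: np.ndarray | None,
    Z_cols: np.ndarray,
    n_iter: int,
    burn_in: int,
    thin: int = 5,
    seed: int = 0,
) -> dict:
    """Single-response mixed model with random intercept and/or slope.

    ``Z_cols`` (n x q) holds the per-observation random-effect design
    (a column of ones for a random intercept, the covariate for a
    random slope).  Species effects have covariance ``G (x) A``; with
    ``A = None`` species are treated as independent (identity).
    Priors: inverse-gamma(0.001, 0.001) on the residual variance and
    on a scalar G; inverse-Wishart(0.002 I, q + 0.002) when q = 2.
    Returns stored draws of beta, G, sigma2, U and the deviance.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    q = Z_cols.shape[1]
    m = int(species_idx.max()) + 1
    A_inv = np.linalg.inv(A) if A is not None else np.eye(m)
    XtX_inv = np.linalg.inv(X.T @ X + 1e-12 * np.eye(p))
    L_x = cholesky(XtX_inv, lower=True)
    a0 = b0 = 0.001
    nu0 = q - 1 + 0.002
    Psi0 = 0.002 * np.eye(q)

    # per-species sums of z z' and index lists
    SZ = np.zeros((m, q, q))
    for i in range(n):
        SZ[species_idx[i]] += np.outer(Z_cols[i], Z_cols[i])

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    U = np.zeros((m, q))
    sigma2 = float(np.var(y - X @ beta)) + 1e-8
    G = np.eye(q) * sigma2 / 2.0

    n_store = (n_iter - burn_in) // thin
    S = {"beta": np.empty((n_store, p)), "G": np.empty((n_store, q, q)),
         "sigma2": np.empty(n_store), "U": np.empty((n_store, m, q)),
         "deviance": np.empty(n_store)}

    def ranef_part(U_):
        return np.einsum("ij,ij->i", Z_cols, U_[species_idx])

    stored = 0
    for it in range(n_iter):
        # beta
        yr = y - ranef_part(U)
        beta_hat = XtX_inv @ (X.T @ yr)
        beta = beta_hat + np.sqrt(sigma2) * (L_x @ rng.standard_normal(p))

        # species effects
        r = y - X @ beta
        Ginv = np.linalg.inv(G)
        P = _kron(Ginv, A_inv)
        b = np.zeros(m * q)
        for a in range(q):
            np.add.at(b, a * m + species_idx, Z_cols[:, a] * r / sigma2)
            for c in range(q):
                idx = np.arange(m)
                P[a * m + idx, c * m + idx] += SZ[:, a, c] / sigma2
        Lp = _chol_psd(_symmetrize(P), "species-effect")
        mean = cho_solve((Lp, True), b)
        draw = mean + solve_triangular(Lp.T, rng.standard_normal(m * q),
                                       lower=False)
        U = draw.reshape((m, q), order="F")

        # G
        if q == 1:
            ss = float(U[:, 0] @ A_inv @ U[:, 0])
            G = np.array([[invgamma.rvs(a0 + m / 2.0, scale=b0 + ss / 2.0,
                                        random_state=rng)]])
        else:
            Sg = U.T @ A_inv @ U
            G = _symmetrize(_invwishart_rvs(nu0 + m, Psi0 + _symmetrize(Sg), rng))

        # residual variance
        e = y - X @ beta - ranef_part(U)
        sigma2 = float(invgamma.rvs(a0 + n / 2.0,
                                    scale=b0 + float(e @ e) / 2.0,
                                    random_state=rng))

        if it >= burn_in and (it - burn_in) % thin == 0 and stored < n_store:
            S["beta"][stored] = beta
            S["G"][stored] = G
            S["sigma2"][stored] = sigma2
            S["U"][stored] = U
            e = y - X @ beta - ranef_part(U)
            S["deviance"][stored] = (
                n * np.log(2 * np.pi * sigma2) + float(e @ e) / sigma2)
            stored += 1

    for key in S:
        S[key] = S[key][:stored]
    beta_m, U_m = S["beta"].mean(0), S["U"].mean(0)
    s2_m = float(S["sigma2"].mean())
    e = y - X @ beta_m - ranef_part(U_m)
    dev_at_mean = n * np.log(2 * np.pi * s2_m) + float(e @ e) / s2_m
    dic, p_d, _ = compute_dic(S["deviance"], dev_at_mean)
    S["dic"], S["p_d"] = dic, p_d
    return S
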