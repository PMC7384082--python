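"""Size scaling of growth rate: mixed regressions on log cell volume.

Tests whether baseline performance (B0 at a reference temperature of
0 or 10 degC) and maximum performance (Bpk) scale with cell volume,
as metabolic scaling theory predicts.  Each response is regressed on
ln(cell volume) with species identity as a random effect on the
intercept, the slope, or both, fitted with and without the
phylogenetic relatedness matrix.  Model quality is summarized by the
marginal and conditional coefficients of determination (Nakagawa &
Schielzeth's Rm^2 and Rc^2), built from the variances explained by
the fixed effects, the random effects, and the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tpcevo.phylo import PhyloCovariance
from tpcevo.pmm import gibbs_univariate, hpd_interval

logger = logging.getLogger(__name__)

RESPONSE_CHOICES = ("b0_tref0", "b0_tref10", "bpk", "ln_b0")
RANDOM_CHOICES = ("intercept", "slope", "both")


@dataclass
class ScalingSummary:
    """Posterior summary of one size-scaling regression."""

    response: str
    random: str
    use_phylogeny: bool
    slope_mean: float
    slope_hpd: tuple
    intercept_mean: float
    intercept_hpd: tuple
    dic: float
    var_fixed: float
    var_random: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float


def r_squared_components(var_fixed: float, var_random: float,
                         var_resid: float) -> tuple[float, float]:
    """Marginal and conditional R^2 from variance components.

    ``Rm^2 = s2_f / (s2_f + s2_r + s2_e)`` and ``Rc^2 = (s2_f + s2_r)
    / (same)``; the fixed-effect variance is the variance of the
    fixed-part linear predictor over the data.
    """
    for v in (var_fixed, var_random, var_resid):
        if v < 0:
            raise ValueError("variance components must be nonnegative")
    total = var_fixed + var_random + var_resid
    if total == 0:
        raise ValueError("all variance components are zero")
    return var_fixed / total, (var_fixed + var_random) / total


def fit_size_scaling(
    data: pd.DataFrame,
    response: str,
    phylo: PhyloCovariance | None = None,
    random: str = "intercept",
    use_phylogeny: bool = False,
    n_iter: int = 4000,
    burn_in: int = 1000,
    thin: int = 2,
    seed: int = 0,
    response_col: str | None = None,
) -> ScalingSummary:
    """Mixed regression of a transformed rate trait on ln cell volume.

    ``data`` needs columns ``taxon_id``, ``cell_volume`` (um^3) and the
    response column (defaults to ``response``).  ``random`` selects the
    species random-effect structure; with ``use_phylogeny`` the species
    effects have covariance proportional to the relatedness matrix.
    A ``ln_b0`` response violates the Gaussian-response assumption on
    which the sampler rests (growth offsets are closer to normal on the
    fourth-root scale); this is logged as a warning, not blocked.
    """
    if random not in RANDOM_CHOICES:
        raise ValueError(f"random must be one of {RANDOM_CHOICES}")
    if response == "ln_b0":
        logger.warning("ln(B0) response departs from the Gaussian "
                       "assumption of the sampler; interpret with care")
    col = response_col or response
    df = data.dropna(subset=[col, "cell_volume"]).copy()
    species = sorted(df["taxon_id"].unique())
    if len(species) < 3:
        raise ValueError("need at least 3 species")
    y = df[col].to_numpy(float)
    x = np.log(df["cell_volume"].to_numpy(float))
    X = np.column_stack([np.ones_like(x), x])

    if use_phylogeny:
        if phylo is None:
            raise ValueError("use_phylogeny=True requires a relatedness matrix")
        order = {t: i for i, t in enumerate(phylo.taxa)}
        missing = [s for s in species if s not in order]
        if missing:
            raise KeyError(f"species not in tree: {missing}")
        sp_idx = df["taxon_id"].map(order).to_numpy(int)
        A = phylo.A
    else:
        order = {s: i for i, s in enumerate(species)}
        sp_idx = df["taxon_id"].map(order).to_numpy(int)
        A = None

    if random == "intercept":
        Z = np.ones((len(df), 1))
    elif random == "slope":
        Z = x[:, None].copy()
    else:
        Z = np.column_stack([np.ones_like(x), x])

    draws = gibbs_univariate(y, X, sp_idx, A, Z, n_iter=n_iter,
                             burn_in=burn_in, thin=thin, seed=seed)

    beta_m = draws["beta"].mean(0)
    G_m = draws["G"].mean(0)
    var_fixed = float(np.var(X @ beta_m - beta_m[0]))  # intercept adds none
    # random-effect variance averaged over the observed random design
    var_random = float(np.mean(np.einsum("ij,jk,ik->i", Z, G_m, Z)))
    var_resid = float(draws["sigma2"].mean())
    r2m, r2c = r_squared_components(var_fixed, var_random, var_resid)
    return ScalingSummary(
        response=response, random=random, use_phylogeny=use_phylogeny,
        slope_mean=float(draws["beta"][:, 1].mean()),
        slope_hpd=hpd_interval(draws["beta"][:, 1]),
        intercept_mean=float(draws["beta"][:, 0].mean()),
        intercept_hpd=hpd_interval(draws["beta"][:, 0]),
        dic=float(draws["dic"]),
        var_fixed=var_fixed, var_random=var_random, var_resid=var_resid,
        r2_marginal=r2m, r2_conditional=r2c,
    )


def scaling_grid(data: pd.DataFrame, response: str,
                 phylo: PhyloCovariance | None = None,
                 seed: int = 0, **chain_kw) -> list[ScalingSummary]:
    """Fit the full random-structure x phylogeny grid for one response.

    Returns all six summaries (intercept / slope / both, with and
    without phylogeny); the best is the minimum-DIC entry with the
    same 0.5-unit tie rule used for the multi-response models.
    """
    out = []
    for use_phylo in (False, True):
        if use_phylo and phylo is None:
            continue
        for random in RANDOM_CHOICES:
            out.append(fit_size_scaling(
                data, response, phylo=phylo, random=random,
                use_phylogeny=use_phylo, seed=seed, **chain_kw))
    return out


def best_scaling(summaries: list[ScalingSummary]) -> ScalingSummary:
    """Minimum-DIC choice; ties under 0.5 go to the simpler structure."""
    best_dic = min(s.dic for s in summaries)
    tied = [s for s in summaries if s.dic - best_dic < 0.5]
    complexity = {"intercept": 1, "slope": 1, "both": 2}
    return min(tied, key=lambda s: (complexity[s.random], s.dic))
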