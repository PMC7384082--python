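"""Normality transforms for the six TPC traits and their uncertainties.

The traits enter the phylogenetic mixed model on transformed scales --
B0^(1/4), ln E, Tpk^2, ln Bpk, ln ED, ln Wop -- chosen to bring each
distribution close to Gaussian.  Variances of the transformed
estimates come from the first-order delta method, var(g(x)) ~=
g'(x)^2 var(x); for B0 = B(Tref) and Bpk = B(Tpk), which are functions
of all four fitted parameters, the inner variance is itself propagated
through the gradient of the curve with respect to the parameter
vector.  Wop has no analytic form (it is found by root search), so its
uncertainty on the ln scale comes from a nonparametric case-resampling
bootstrap of the underlying series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from tpcevo.tpc_core import TPCParams, evaluate_tpc
from tpcevo.tpc_fit import TRAIT_ORDER, FitResult, GrowthRateSeries, fit_sharpe_schoolfield

logger = logging.getLogger(__name__)

#: canonical names of the six transformed traits, in model order
TRAIT_NAMES = ("b0_qrt", "ln_e", "tpk_sq", "ln_bpk", "ln_ed", "ln_wop")


@dataclass(frozen=True)
class TraitVector:
    """Six transformed TPC traits with measurement-error variances.

    ``values`` and ``se_variances`` follow :data:`TRAIT_NAMES` order;
    ``missing_mask`` marks traits the fit could not support.  A trait
    may have a finite value but a missing (NaN) variance when the fit
    Jacobian was singular.
    """

    taxon_id: str
    values: np.ndarray
    se_variances: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("values", "se_variances", "missing_mask"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.values.shape != (6,):
            raise ValueError("expected 6 traits")


def _param_vector(params: TPCParams) -> np.ndarray:
    return np.array([params.b0, params.e_act, params.t_pk, params.e_d])


def _curve_at(theta: np.ndarray, t_ref: float, which: str) -> float:
    p = TPCParams(b0=theta[0], e_act=theta[1], t_pk=theta[2], e_d=theta[3],
                  t_ref=t_ref)
    temp = p.t_ref if which == "ref" else p.t_pk
    return evaluate_tpc(p, temp)


def _grad(theta: np.ndarray, t_ref: float, which: str) -> np.ndarray:
    """Central-difference gradient of B(Tref) or B(Tpk) w.r.t. the four
    fitted parameters (the Tpk entry includes the moving-argmax term,
    which vanishes to first order since dB/dT = 0 at the peak)."""
    g = np.empty(4)
    for i in range(4):
        h = 1e-6 * max(abs(theta[i]), 1e-8)
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        g[i] = (_curve_at(up, t_ref, which) - _curve_at(dn, t_ref, which)) / (2 * h)
    return g


def transform_values(b0: float, e: float, t_pk: float, b_pk: float,
                     e_d: float, w_op: float) -> np.ndarray:
    """Forward transform of the six traits (NaN passes through)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.array([
            b0 ** 0.25, np.log(e), t_pk ** 2,
            np.log(b_pk), np.log(e_d), np.log(w_op),
        ])


def back_transform_values(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`transform_values` (same trait order)."""
    return np.array([
        v[0] ** 4, np.exp(v[1]), np.sqrt(v[2]),
        np.exp(v[3]), np.exp(v[4]), np.exp(v[5]),
    ])


def transform_traits(fit: FitResult) -> TraitVector:
    """Build the transformed 6-trait vector for one converged fit.

    Delta-method variances use the least-squares parameter covariance;
    the ln Wop variance slot is left NaN here and filled by
    :func:`bootstrap_wop_variance`.  Non-finite variances are recorded
    as NaN with the value retained.
    """
    if not fit.converged or fit.params is None or fit.derived is None:
        raise ValueError("transform_traits requires a converged fit")
    p, d = fit.params, fit.derived
    values = transform_values(d.b_at_ref, p.e_act, p.t_pk, d.b_pk, p.e_d, d.w_op)
    variances = np.full(6, np.nan)
    cov = fit.param_covariance
    if cov is not None and np.all(np.isfinite(cov)):
        theta = _param_vector(p)
        var_e, var_tpk, var_ed = cov[1, 1], cov[2, 2], cov[3, 3]
        g_ref = _grad(theta, p.t_ref, "ref")
        g_pk = _grad(theta, p.t_ref, "pk")
        var_b0 = float(g_ref @ cov @ g_ref)
        var_bpk = float(g_pk @ cov @ g_pk)
        # var(g(x)) ~= g'(x)^2 var(x)
        variances[0] = (0.25 * d.b_at_ref ** -0.75) ** 2 * var_b0
        variances[1] = var_e / p.e_act ** 2
        variances[2] = (2.0 * p.t_pk) ** 2 * var_tpk
        variances[3] = var_bpk / d.b_pk ** 2
        variances[4] = var_ed / p.e_d ** 2
    variances[~np.isfinite(variances)] = np.nan
    variances[5] = np.nan  # ln Wop: bootstrap only
    mask = np.array([fit.trait_missing(t) for t in TRAIT_ORDER])
    mask |= ~np.isfinite(values)
    return TraitVector(taxon_id=fit.taxon_id, values=values,
                       se_variances=variances, missing_mask=mask)


def bootstrap_wop_variance(
    series: GrowthRateSeries,
    fit: FitResult,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Case-resampling bootstrap variance of ln Wop.

    Resamples (temperature, rate) pairs with replacement, refits from
    the original optimum, and recomputes ln Wop per replicate.
    Returns ``(variance, convergence_fraction)``; the variance is NaN
    when fewer than half the replicates yield a usable Wop.
    """
    if not fit.converged or fit.params is None:
        raise ValueError("bootstrap requires a converged fit")
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    rng = np.random.default_rng(seed)
    n = series.n_points
    theta_hat = _param_vector(fit.params)
    ln_wops = []
    n_ok = 0
    from dataclasses import replace as _replace

    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        idx.sort()
        boot = _replace(series, temperatures=series.temperatures[idx],
                        rates=series.rates[idx])
        res = fit_sharpe_schoolfield(boot, fit.params.t_ref,
                                     starts=[theta_hat])
        if res.converged and res.derived is not None and np.isfinite(res.derived.w_op):
            ln_wops.append(np.log(res.derived.w_op))
            n_ok += 1
    frac = n_ok / n_boot
    if frac < 0.5:
        logger.warning("%s: only %.0f%% of bootstrap replicates converged; "
                       "ln Wop variance recorded as missing",
                       series.taxon_id, 100 * frac)
        return float("nan"), frac
    return float(np.var(ln_wops, ddof=1)), frac
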