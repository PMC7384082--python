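"""Per-taxon Sharpe--Schoolfield fitting with quality filters.

Each growth-rate-versus-temperature series is preprocessed (nonpositive
rates dropped -- the model can only produce positive rates), fitted by
bounded nonlinear least squares from a small multi-start schedule, and
then screened: fits with R^2 < 0.5 are discarded, and for a reference
temperature of 10 degC fits whose peak lies below 10 degC are discarded
as well (their "B0" would be read off the falling branch).  Parameters
whose supporting data region is absent (e.g. no measurements above the
peak) are flagged missing so the downstream mixed model can impute
them under a missing-at-random assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from tpcevo.tpc_core import (
    BOLTZMANN_EV,
    DerivedTPC,
    TPCParams,
    derive_tpc,
    evaluate_tpc,
)

logger = logging.getLogger(__name__)

#: minimum number of positive points required to attempt a fit
MIN_POINTS = 4

#: default R^2 cutoff below which a fit is discarded
DEFAULT_MIN_R2 = 0.5

#: six TPC traits, in canonical order (transformed downstream as
#: B0^1/4, ln E, Tpk^2, ln Bpk, ln ED, ln Wop)
TRAIT_ORDER = ("b0", "e_act", "t_pk", "b_pk", "e_d", "w_op")


class InsufficientDataError(ValueError):
    """Fewer than MIN_POINTS positive measurements remain."""


@dataclass(frozen=True)
class GrowthRateSeries:
    """One taxon's growth-rate measurements across temperatures.

    Temperatures in kelvin, rates in s^-1 (conversion from degC /
    per-day happens on CSV read).  ``habitat`` is one of ``marine``,
    ``freshwater`` or ``unknown``.
    """

    taxon_id: str
    temperatures: np.ndarray
    rates: np.ndarray
    habitat: str = "unknown"
    latitude: float | None = None
    longitude: float | None = None
    cell_volume: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("temperatures and rates must be equal-length 1-D")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "rates", r)

    @property
    def n_points(self) -> int:
        return int(self.temperatures.size)


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one series: parameters, derived traits, quality."""

    taxon_id: str
    params: TPCParams | None
    derived: DerivedTPC | None
    param_covariance: np.ndarray | None
    r_squared: float
    n_points: int
    converged: bool
    missing_mask: dict = field(default_factory=dict)
    saturated: bool = False

    def trait_missing(self, trait: str) -> bool:
        return bool(self.missing_mask.get(trait, not self.converged))


def preprocess(series: GrowthRateSeries) -> tuple[GrowthRateSeries, int]:
    """Drop nonpositive rates and sort by temperature.

    Returns the cleaned series and the number of points removed.
    Raises :class:`InsufficientDataError` when fewer than four positive
    points remain (four free parameters).
    """
    keep = series.rates > 0
    n_removed = int((~keep).sum())
    t = series.temperatures[keep]
    r = series.rates[keep]
    if t.size < MIN_POINTS:
        raise InsufficientDataError(
            f"{series.taxon_id}: only {t.size} positive points "
            f"(need >= {MIN_POINTS})"
        )
    order = np.argsort(t)
    cleaned = replace(series, temperatures=t[order], rates=r[order])
    return cleaned, n_removed


def _bounds(temps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # generous physical ranges keeping the optimizer away from singularities;
    # ED lower bound is enforced relative to E inside the residual instead
    lo = np.array([1e-10, 1e-2, temps.min() - 10.0, 1e-3])
    hi = np.array([1e3, 10.0, temps.max() + 10.0, 50.0])
    return lo, hi


def _residuals(theta: np.ndarray, temps: np.ndarray, rates: np.ndarray,
               t_ref: float) -> np.ndarray:
    b0, e, t_pk, e_d = theta
    k = BOLTZMANN_EV
    gap = e_d - e
    if gap < 1e-6:
        # smooth penalty wall instead of a hard failure so the solver
        # can back out of the ED <= E region
        return np.full_like(rates, 1e3 * (1e-6 - gap) + 1e3)
    num = b0 * np.exp(-(e / k) * (1.0 / temps - 1.0 / t_ref))
    den = 1.0 + (e / gap) * np.exp((e_d / k) * (1.0 / t_pk - 1.0 / temps))
    return num / den - rates


def _start_points(series: GrowthRateSeries, t_ref: float):
    """Multi-start schedule: E in {0.3, 0.65, 1.2} eV, Tpk at the observed
    maximum and +/- 3 K, ED = 3E, b0 from the rate nearest Tref scaled by
    the Arrhenius factor."""
    temps, rates = series.temperatures, series.rates
    t_at_max = temps[int(np.argmax(rates))]
    i_near = int(np.argmin(np.abs(temps - t_ref)))
    k = BOLTZMANN_EV
    for e0 in (0.3, 0.65, 1.2):
        b0_0 = rates[i_near] * np.exp(
            (e0 / k) * (1.0 / temps[i_near] - 1.0 / t_ref)
        )
        b0_0 = float(np.clip(b0_0, 1e-9, 1e2))
        for dt in (0.0, 3.0, -3.0):
            yield np.array([b0_0, e0, t_at_max + dt, 3.0 * e0])


def fit_sharpe_schoolfield(
    series: GrowthRateSeries,
    t_ref: float,
    starts=None,
) -> FitResult:
    """Bounded least-squares fit of the Sharpe--Schoolfield model.

    The best (lowest SSR) of a multi-start schedule is returned; ties
    are broken toward lower activation energy.  The parameter
    covariance is the standard Gauss--Newton estimate
    ``SSR/(n-4) * (J'J)^-1`` at the optimum.

    Parameters
    ----------
    series
        Preprocessed series (positive rates, sorted temperatures).
    t_ref
        Reference temperature in kelvin.
    starts
        Optional iterable of explicit start vectors ``(b0, E, Tpk,
        ED)`` overriding the default schedule.
    """
    temps, rates = series.temperatures, series.rates
    n = temps.size
    if n < MIN_POINTS:
        raise InsufficientDataError(f"{series.taxon_id}: {n} points")
    lo, hi = _bounds(temps)
    best = None
    if starts is None:
        starts = _start_points(series, t_ref)
    for theta0 in starts:
        theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(
                _residuals, theta0, bounds=(lo, hi),
                args=(temps, rates, t_ref), method="trf", x_scale="jac",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
            )
        except Exception:  # pragma: no cover - solver blow-up
            continue
        if not sol.success or sol.x[3] - sol.x[1] < 1e-6:
            continue
        ssr = float(2.0 * sol.cost)
        if (best is None or ssr < best[0] - 1e-14 * (1 + best[0])
                or (abs(ssr - best[0]) <= 1e-14 * (1 + best[0])
                    and sol.x[1] < best[1].x[1])):
            best = (ssr, sol)
    if best is None:
        return FitResult(
            taxon_id=series.taxon_id, params=None, derived=None,
            param_covariance=None, r_squared=float("nan"),
            n_points=n, converged=False,
            missing_mask={t: True for t in TRAIT_ORDER},
        )
    ssr, sol = best
    b0, e, t_pk, e_d = sol.x
    params = TPCParams(b0=b0, e_act=e, t_pk=t_pk, e_d=e_d, t_ref=t_ref)
    derived = derive_tpc(params)
    sst = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    saturated = n == MIN_POINTS
    if saturated:
        logger.warning("%s: saturated fit (exactly %d points)",
                       series.taxon_id, MIN_POINTS)
    cov = None
    dof = n - 4
    if dof > 0:
        J = sol.jac
        JTJ = J.T @ J
        try:
            cov = (ssr / dof) * np.linalg.inv(JTJ)
        except np.linalg.LinAlgError:
            cov = (ssr / dof) * np.linalg.pinv(JTJ)
    result = FitResult(
        taxon_id=series.taxon_id, params=params, derived=derived,
        param_covariance=cov, r_squared=r2, n_points=n,
        converged=True, saturated=saturated,
        missing_mask={t: False for t in TRAIT_ORDER},
    )
    return mark_uncertain_params(result, series)


def mark_uncertain_params(result: FitResult, series: GrowthRateSeries) -> FitResult:
    """Flag parameters lacking supporting data coverage as missing.

    Coverage rules: E needs >= 3 points below the fitted peak; Tpk and
    ED need >= 2 points above it; B0 inherits missingness from E (the
    rise is unconstrained without it).  Derived traits inherit: Bpk is
    missing if Tpk is, Wop if E or Tpk is.  A non-converged fit has all
    six traits missing.
    """
    if not result.converged or result.params is None:
        return replace(result, missing_mask={t: True for t in TRAIT_ORDER})
    t_pk = result.params.t_pk
    n_below = int((series.temperatures < t_pk).sum())
    n_above = int((series.temperatures > t_pk).sum())
    mask = {t: False for t in TRAIT_ORDER}
    if n_below < 3:
        mask["e_act"] = True
    if n_above < 2:
        mask["t_pk"] = True
        mask["e_d"] = True
    if mask["e_act"]:
        mask["b0"] = True
    if mask["t_pk"]:
        mask["b_pk"] = True
    if mask["e_act"] or mask["t_pk"]:
        mask["w_op"] = True
    if result.derived is not None and np.isnan(result.derived.w_op):
        mask["w_op"] = True
    return replace(result, missing_mask=mask)


def filter_fits(
    results: list[FitResult],
    t_ref: float,
    min_r2: float = DEFAULT_MIN_R2,
) -> list[FitResult]:
    """Apply quality filters and log how many fits each rule removed.

    Drops non-converged fits and fits with ``r_squared < min_r2``.
    When ``t_ref`` is 10 degC (283.15 K) additionally drops fits with
    ``t_pk`` below 283.15 K, where B0 would no longer sit on the
    rising branch.  Idempotent.
    """
    kept: list[FitResult] = []
    n_unconverged = n_r2 = n_tpk = 0
    tpk_rule = abs(t_ref - 283.15) < 1e-9
    for res in results:
        if not res.converged or res.params is None:
            n_unconverged += 1
            continue
        if not np.isfinite(res.r_squared) or res.r_squared < min_r2:
            n_r2 += 1
            continue
        if tpk_rule and res.params.t_pk < 283.15:
            n_tpk += 1
            continue
        kept.append(res)
    logger.info(
        "filter_fits: kept %d/%d (dropped %d unconverged, %d below R2=%.2f, "
        "%d with Tpk < 283.15 K)",
        len(kept), len(results), n_unconverged, n_r2, min_r2, n_tpk,
    )
    return kept


def read_rates_csv(path) -> list[GrowthRateSeries]:
    """Read a growth-rate CSV into per-taxon series.

    Expected columns: ``taxon_id, temperature_C, rate, rate_unit,
    habitat, latitude, longitude, cell_volume_um3`` (header required;
    missing values empty).  Temperatures are converted to kelvin and
    rates to s^-1 (``rate_unit`` is ``per_day`` or ``per_second``).
    """
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for taxon, grp in df.groupby("taxon_id", sort=True):
        unit = grp["rate_unit"].iloc[0] if "rate_unit" in grp else "per_second"
        scale = 1.0 / 86400.0 if unit == "per_day" else 1.0
        first = grp.iloc[0]

        def _opt(col):
            if col not in grp or pd.isna(first[col]):
                return None
            return float(first[col])

        out.append(GrowthRateSeries(
            taxon_id=str(taxon),
            temperatures=grp["temperature_C"].to_numpy(float) + 273.15,
            rates=grp["rate"].to_numpy(float) * scale,
            habitat=str(first.get("habitat", "unknown") or "unknown"),
            latitude=_opt("latitude"),
            longitude=_opt("longitude"),
            cell_volume=_opt("cell_volume_um3"),
        ))
    return out
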