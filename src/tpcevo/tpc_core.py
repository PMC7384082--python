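"""Closed-form evaluation of the Sharpe--Schoolfield thermal performance curve.

The four-parameter variant with the peak temperature as an explicit
parameter is

    B(T) = b0 * exp(-E/k * (1/T - 1/Tref))
           / (1 + E/(ED - E) * exp(ED/k * (1/Tpk - 1/T)))

where ``b0`` sets the vertical offset (the rate at the reference
temperature ``Tref``, on the rising branch), ``E`` (eV) the steepness of
the rise, ``Tpk`` (K) the temperature of maximal rate, and ``ED`` (eV)
the steepness of the high-temperature fall.  Under this
parameterization ``Tpk`` is the exact argmax of the curve, and two
derived quantities describe its shape: the maximum height ``Bpk =
B(Tpk)`` and the operational niche width ``Wop = Tpk - T_half`` where
``T_half`` is the rising-branch temperature at which the rate equals
``Bpk / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: Boltzmann constant in eV/K.
BOLTZMANN_EV = 8.617e-5

#: minimum allowed gap between deactivation and activation energy (eV);
#: the denominator factor E/(ED - E) blows up as ED -> E.
_MIN_ED_GAP = 1e-6

#: default search window below Tpk for the half-height temperature (K).
WOP_SEARCH_SPAN = 150.0


class TPCValidationError(ValueError):
    """A TPC parameter set violates a model invariant."""


class HalfHeightNotReachedError(ValueError):
    """The rising branch never falls to Bpk/2 within the search window."""


@dataclass(frozen=True)
class TPCParams:
    """Parameters of the explicit-Tpk Sharpe--Schoolfield model.

    Parameters
    ----------
    b0
        Rate (time^-1) at the reference temperature, pre-deactivation.
    e_act
        Activation energy E (eV); thermal sensitivity of the rise.
    t_pk
        Peak temperature Tpk (K).
    e_d
        Deactivation energy ED (eV); must exceed ``e_act``.
    t_ref
        Reference temperature Tref (K).
    """

    b0: float
    e_act: float
    t_pk: float
    e_d: float
    t_ref: float

    def __post_init__(self) -> None:
        if not self.b0 > 0:
            raise TPCValidationError(f"b0 must be > 0, got {self.b0}")
        if not self.e_act > 0:
            raise TPCValidationError(f"e_act must be > 0, got {self.e_act}")
        if not self.t_pk > 0:
            raise TPCValidationError(f"t_pk must be > 0, got {self.t_pk}")
        if not self.t_ref > 0:
            raise TPCValidationError(f"t_ref must be > 0, got {self.t_ref}")
        if not self.e_d - self.e_act >= _MIN_ED_GAP:
            raise TPCValidationError(
                "e_d must exceed e_act by at least "
                f"{_MIN_ED_GAP} eV (e_d={self.e_d}, e_act={self.e_act}); "
                "the factor E/(ED-E) must be positive and finite"
            )


@dataclass(frozen=True)
class DerivedTPC:
    """Shape quantities derived from a fitted TPC.

    ``b_pk`` is the maximum height of the curve, ``w_op`` the
    operational niche width (K) and ``b_at_ref`` the curve value at the
    reference temperature (reported downstream as the trait "B0").
    ``w_op`` is NaN when the half-height point lies outside the
    physical search window.
    """

    b_pk: float
    w_op: float
    b_at_ref: float


def evaluate_tpc(params: TPCParams, temperature):
    """Evaluate the Sharpe--Schoolfield curve at ``temperature`` (K).

    Accepts a scalar or array temperature; all temperatures must be
    positive.  The returned rate is strictly positive everywhere.
    """
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    k = BOLTZMANN_EV
    num = params.b0 * np.exp(-(params.e_act / k) * (1.0 / T - 1.0 / params.t_ref))
    gap = params.e_d - params.e_act
    den = 1.0 + (params.e_act / gap) * np.exp(
        (params.e_d / k) * (1.0 / params.t_pk - 1.0 / T)
    )
    out = num / den
    if np.ndim(temperature) == 0:
        return float(out)
    return out


def compute_bpk(params: TPCParams) -> float:
    """Maximum height of the curve, ``B(Tpk)``.

    ``Tpk`` is the exact argmax under this parameterization, so no
    numerical search is needed.
    """
    return evaluate_tpc(params, params.t_pk)


def compute_b_at_ref(params: TPCParams) -> float:
    """Curve value at the reference temperature, ``B(Tref)``.

    The fitted ``b0`` only approximates the curve value at ``Tref``
    (the deactivation denominator is not exactly 1 there), so the trait
    used downstream under the name "B0" is this manual evaluation.
    """
    return evaluate_tpc(params, params.t_ref)


def compute_wop(params: TPCParams, search_floor: float | None = None) -> float:
    """Operational niche width ``Wop = Tpk - T_half`` (K).

    ``T_half`` is the unique temperature on the rising branch where the
    rate is half the maximum, found by bracketed root finding to a
    tolerance of 1e-6 K.  ``search_floor`` (default ``t_pk - 150``)
    bounds the search below; if the curve has not dropped to half
    height by then, :class:`HalfHeightNotReachedError` is raised and
    the caller should record Wop as missing rather than extrapolate
    into an unphysical range.
    """
    if search_floor is None:
        search_floor = params.t_pk - WOP_SEARCH_SPAN
    if search_floor >= params.t_pk:
        raise ValueError("search_floor must be below t_pk")
    if search_floor <= 0:
        search_floor = min(1.0, params.t_pk / 2.0)
    half = compute_bpk(params) / 2.0

    def f(T: float) -> float:
        return evaluate_tpc(params, T) - half

    if f(search_floor) > 0:
        raise HalfHeightNotReachedError(
            "half-height not reached above the search floor "
            f"({search_floor:.2f} K); record Wop as missing"
        )
    t_half = brentq(f, search_floor, params.t_pk, xtol=1e-6)
    return params.t_pk - t_half


def derive_tpc(params: TPCParams, search_floor: float | None = None) -> DerivedTPC:
    """Compute all derived shape quantities; Wop becomes NaN if unreachable."""
    b_pk = compute_bpk(params)
    b_at_ref = compute_b_at_ref(params)
    try:
        w_op = compute_wop(params, search_floor)
    except HalfHeightNotReachedError:
        w_op = float("nan")
    return DerivedTPC(b_pk=b_pk, w_op=w_op, b_at_ref=b_at_ref)
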