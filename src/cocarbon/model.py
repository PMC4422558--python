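"""Core model of carbon-limited growth under cAMP-Crp catabolite repression.

The model describes *E. coli* in steady-state exponential growth on one or
more co-utilized carbon substrates, all at saturating concentration.  Its
backbone is the empirical "C-line": the expression level ``E`` of any
cAMP-Crp-activated catabolic operon falls linearly with the growth rate
``lambda``,

    E(lambda) = E0 * (1 - lambda / lambda_c),

where ``lambda_c`` (about 1.16/h for the reference K-12 strain) is the
horizontal intercept and acts as a "speed limit" for carbon-limited growth.
Because the alpha-ketoacid pool that inhibits cAMP synthesis senses the
*total* carbon influx, the same C-line governs each substrate's uptake
system during mixed growth.

Combining the C-line with a linear flux-to-growth relation gives each
substrate a single composite *capacity* parameter ``a_i`` (units 1/h): the
growth contribution it would support at zero catabolite repression.  The
growth rate supported by any set of capacities is

    lambda = S / (1 + S / lambda_c),    S = sum_i a_i,

and for a single substrate the measurable rate ``lambda_i`` determines the
capacity as ``a_i = lambda_i / (1 - lambda_i / lambda_c)``.  Eliminating the
capacities yields the growth-rate composition formula implemented by
:func:`compose_growth_rates`, which predicts the mixed-substrate growth rate
from the single-substrate rates alone, with ``lambda_c`` the only parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "LAMBDA_C_DEFAULT",
    "CompositionModel",
    "SpeedLimitError",
    "effective_capacity",
    "single_rate_from_capacity",
    "compose_growth_rates",
    "cline_expression",
    "uptake_flux_ratio",
    "solve_steady_state",
]

#: Published C-line horizontal intercept for E. coli K-12 NCM3722, 1/h.
LAMBDA_C_DEFAULT = 1.16


class SpeedLimitError(ValueError):
    """A growth rate at or above the carbon-limited speed limit ``lambda_c``.

    The capacity transform diverges as ``lambda -> lambda_c``; the model
    excludes carbon-limited growth at or beyond the speed limit.
    """


@dataclass(frozen=True)
class CompositionModel:
    """The one-parameter growth model: the speed limit ``lambda_c`` in 1/h."""

    lambda_c: float = LAMBDA_C_DEFAULT

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lambda_c) and self.lambda_c > 0):
            raise ValueError(
                f"lambda_c must be a finite positive rate (1/h), got {self.lambda_c!r}"
            )


def _as_model(model: CompositionModel | None) -> CompositionModel:
    return CompositionModel() if model is None else model


def _check_rate(
    rate: float,
    lambda_c: float,
    *,
    allow_limit: bool = False,
    name: str = "rate",
) -> float:
    rate = float(rate)
    if not math.isfinite(rate) or rate < 0:
        raise ValueError(f"{name} must be a finite non-negative growth rate, got {rate!r}")
    at_limit = rate >= lambda_c if not allow_limit else rate > lambda_c
    if at_limit:
        raise SpeedLimitError(
            f"{name} = {rate}/h is at or above the carbon-limited speed limit "
            f"lambda_c = {lambda_c}/h; the model does not describe such growth"
        )
    return rate


def effective_capacity(rate: float, model: CompositionModel | None = None) -> float:
    """Capacity ``a = lambda / (1 - lambda/lambda_c)`` of a single substrate.

    Inverts the single-substrate growth relation: the composite capacity
    (carbon efficiency x kinetic constant x unrepressed expression, 1/h)
    that reproduces the observed single-substrate growth rate.  Strictly
    increasing in ``rate`` and divergent as the rate approaches the speed
    limit.

    Raises
    ------
    SpeedLimitError
        If ``rate >= lambda_c``.
    ValueError
        If ``rate`` is negative or non-finite.
    """
    m = _as_model(model)
    rate = _check_rate(rate, m.lambda_c)
    return rate / (1.0 - rate / m.lambda_c)


def single_rate_from_capacity(capacity: float, model: CompositionModel | None = None) -> float:
    """Growth rate ``lambda = a / (1 + a/lambda_c)`` on a single substrate.

    Algebraic inverse of :func:`effective_capacity`; always returns a rate
    in ``[0, lambda_c)``.
    """
    m = _as_model(model)
    capacity = float(capacity)
    if not math.isfinite(capacity) or capacity < 0:
        raise ValueError(f"capacity must be finite and non-negative, got {capacity!r}")
    return capacity / (1.0 + capacity / m.lambda_c)


def compose_growth_rates(
    rates: Sequence[float] | Iterable[float],
    model: CompositionModel | None = None,
) -> float:
    """Predict the growth rate on co-utilized substrates from single rates.

    The growth-rate composition formula: with ``S = sum_i a_i`` the summed
    effective capacities of the individual substrates,

        lambda_mix = S / (1 + S / lambda_c).

    The prediction needs no parameter beyond ``lambda_c``.  The result is
    at least ``max(rates)``, below ``sum(rates)`` whenever two rates are
    positive, and always below the speed limit ``lambda_c``.  The model
    states the two-substrate case; lists of three or more substrates are
    the natural extension of the same flux argument.

    Raises
    ------
    SpeedLimitError
        If any rate is at or above ``lambda_c``.
    ValueError
        For an empty list or a negative rate.
    """
    m = _as_model(model)
    rate_list = [ _check_rate(r, m.lambda_c) for r in rates ]
    if not rate_list:
        raise ValueError("compose_growth_rates requires at least one growth rate")
    # fsum keeps the result exactly permutation-invariant
    total = math.fsum(r / (1.0 - r / m.lambda_c) for r in rate_list)
    return total / (1.0 + total / m.lambda_c)


def cline_expression(
    rate: float,
    e0: float,
    model: CompositionModel | None = None,
) -> float:
    """Catabolic expression ``E = E0 (1 - lambda/lambda_c)`` on the C-line.

    ``e0`` is the operon-specific unrepressed expression level (vertical
    intercept, arbitrary positive units such as Miller units per OD).  The
    same line applies during single- and mixed-substrate growth, which is
    what lets one C-line calibrate the whole composition model.  Valid for
    ``0 <= rate <= lambda_c`` (the expression vanishes at the limit).
    """
    m = _as_model(model)
    rate = _check_rate(rate, m.lambda_c, allow_limit=True)
    e0 = float(e0)
    if not math.isfinite(e0) or e0 < 0:
        raise ValueError(f"e0 must be finite and non-negative, got {e0!r}")
    return e0 * (1.0 - rate / m.lambda_c)


def uptake_flux_ratio(
    rate_single: float,
    rate_mixed: float,
    model: CompositionModel | None = None,
) -> float:
    """Fold-change of a substrate's uptake flux between mixed and single growth.

    Because uptake flux is proportional to catabolic enzyme expression,
    which sits on the C-line at the realized growth rate,

        J(mixed) / J(single) = (1 - lambda_mixed/lambda_c)
                             / (1 - lambda_single/lambda_c).

    Below 1 whenever the mixture grows faster than the single substrate:
    co-utilization *reduces* the uptake of each individual substrate, the
    signature of the shared cAMP-Crp negative feedback.
    """
    m = _as_model(model)
    rate_single = _check_rate(rate_single, m.lambda_c, name="rate_single")
    rate_mixed = _check_rate(rate_mixed, m.lambda_c, name="rate_mixed")
    return (1.0 - rate_mixed / m.lambda_c) / (1.0 - rate_single / m.lambda_c)


def solve_steady_state(
    capacities: Sequence[float] | Iterable[float],
    model: CompositionModel | None = None,
    *,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> float:
    """Steady-state growth rate of the full feedback system, by iteration.

    Solves ``lambda = (1 - lambda/lambda_c) * sum(capacities)`` — the
    closed loop of uptake flux, flux-to-growth and C-line repression — by
    damped fixed-point iteration from ``lambda = 0``.  The equation is
    linear, so the closed form ``S/(1+S/lambda_c)`` solves it exactly; this
    routine exists as an independent numerical oracle for that formula and
    must agree with it to within ``tol``.

    The damping factor is ``min(0.5, 0.9/(1 + S/lambda_c))``, which makes
    the iteration a contraction for every capacity sum ``S >= 0`` (a fixed
    damping of 0.5 diverges once ``S > 3 lambda_c``).

    Raises
    ------
    ArithmeticError
        If the residual has not dropped below ``tol`` after ``max_iter``
        iterations (cannot occur for valid finite inputs).
    """
    m = _as_model(model)
    caps = []
    for c in capacities:
        c = float(c)
        if not math.isfinite(c) or c < 0:
            raise ValueError(f"capacities must be finite and non-negative, got {c!r}")
        caps.append(c)
    total = math.fsum(caps)
    damping = min(0.5, 0.9 / (1.0 + total / m.lambda_c))
    lam = 0.0
    for _ in range(max_iter):
        target = (1.0 - lam / m.lambda_c) * total
        lam = (1.0 - damping) * lam + damping * target
        if abs(lam - (1.0 - lam / m.lambda_c) * total) <= tol:
            return lam
    raise ArithmeticError(
        f"fixed-point iteration did not reach residual {tol} in {max_iter} steps"
    )
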