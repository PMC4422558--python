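"""Synthetic growth studies and C-line data for testing and calibration.

The generator emulates the shape of the reference study: a handful of
carbon substrates with single-substrate growth rates in (0.3, 0.95)/h, all
unordered pairs of interest measured once, and about 5% multiplicative
between-replicate variability.  Mixed-substrate "truth" comes from the
composition formula itself; pairs flagged group B additionally have one
substrate's effective capacity suppressed by a constant factor, a minimal
stand-in for inducer-exclusion-like uptake interference (no mechanistic
fidelity claimed).  Observed rates are the truth times a log-normal noise
factor with unit mean, keeping rates positive.

``recover_lambda_c`` closes the loop: it re-estimates the speed-limit
parameter from a (synthetic or real) growth table by one-dimensional least
squares over the group-A pairs, with a parametric-bootstrap interval that
respects the noise shared between pairs through the single-rate
measurements.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar

from .analysis import GrowthTable, PairObservation
from .cline import CLinePoint
from .model import CompositionModel, single_rate_from_capacity

__all__ = [
    "SyntheticConfig",
    "generate_growth_study",
    "generate_cline_points",
    "recover_lambda_c",
    "LambdaCEstimate",
    "UninformativeDataError",
]

logger = logging.getLogger(__name__)

#: Default seed for the pair-resampling bootstrap in :func:`recover_lambda_c`.
DEFAULT_RECOVERY_SEED = 20150411


class UninformativeDataError(ValueError):
    """The least-squares objective does not identify lambda_c from these data.

    Raised when the objective is numerically constant over the search
    bracket or its minimizer sits on a bracket endpoint (e.g. measured
    mixed rates at or above the sum of the single rates, which pushes the
    estimate to the upper bound).
    """


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design for :func:`generate_growth_study`.

    Defaults mirror the reference study: 8 substrates split into 3 "lower"
    and 5 "upper", single rates uniform on (0.30, 0.95)/h, 5% multiplicative
    replicate noise, and a capacity suppression factor of 0.2 acting on
    group-B pairs (1.0 turns the interaction off).  The default emulates the
    strong uptake interference seen in the reference study, where a group-B
    pair's mixed rate falls near the faster substrate's single rate.

    ``pair_design`` is ``"bipartite"`` (lower x upper pairs are group A,
    upper x upper pairs are group B) or ``"all_pairs"`` (every pair, all
    group A, no suppression).
    """

    n_substrates: int = 8
    n_lower: int = 3
    lambda_c_true: float = 1.16
    single_rate_range: tuple[float, float] = (0.30, 0.95)
    noise_cv: float = 0.05
    suppression_factor: float = 0.2
    pair_design: str = "bipartite"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair_design not in ("bipartite", "all_pairs"):
            raise ValueError(
                f"pair_design must be 'bipartite' or 'all_pairs', got {self.pair_design!r}"
            )
        if self.n_substrates < 2:
            raise ValueError("need at least 2 substrates")
        if self.pair_design == "bipartite" and not (0 < self.n_lower < self.n_substrates):
            raise ValueError(
                f"bipartite design needs 0 < n_lower < n_substrates, got "
                f"n_lower={self.n_lower}, n_substrates={self.n_substrates}"
            )
        lo, hi = self.single_rate_range
        if not (0 < lo < hi < self.lambda_c_true):
            raise ValueError(
                f"single_rate_range must lie inside (0, lambda_c_true), got {self.single_rate_range}"
            )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0 <= self.suppression_factor <= 1):
            raise ValueError("suppression_factor must be in [0, 1]")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean log-normal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def _noisy_rate(true_rate: float, factors, lambda_c: float) -> float:
    """Apply the next noise factor, redrawing past the speed limit (rare)."""
    for f in factors:
        value = true_rate * f
        if value < lambda_c:
            return value
    raise AssertionError("noise stream exhausted")  # pragma: no cover


def generate_growth_study(config: SyntheticConfig) -> GrowthTable:
    """Draw a synthetic growth study under the composition model.

    True single rates are uniform on ``single_rate_range``; true mixed
    rates follow the composition formula on the corresponding capacities,
    with the slower member's capacity multiplied by ``suppression_factor``
    in group-B pairs (the faster substrate interferes with the slower one's
    uptake, as glucose does via inducer exclusion).  Observed rates are
    truth times unit-mean log-normal noise.  Deterministic for a given
    config; noise factors that would push an observation past
    ``lambda_c_true`` are redrawn (a multi-sigma event at 5% noise).
    """
    model = CompositionModel(config.lambda_c_true)
    ss = np.random.SeedSequence(config.seed)
    rng_rates, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    if config.pair_design == "bipartite":
        names = [f"lower_{i+1}" for i in range(config.n_lower)] + [
            f"upper_{i+1}" for i in range(config.n_substrates - config.n_lower)
        ]
    else:
        names = [f"substrate_{i+1}" for i in range(config.n_substrates)]
    lo, hi = config.single_rate_range
    true_singles = dict(zip(names, rng_rates.uniform(lo, hi, size=len(names))))

    if config.pair_design == "bipartite":
        lowers, uppers = names[: config.n_lower], names[config.n_lower :]
        pair_plan = [(a, b, "A") for a in lowers for b in uppers]
        pair_plan += [(a, b, "B") for a, b in itertools.combinations(uppers, 2)]
    else:
        pair_plan = [(a, b, "A") for a, b in itertools.combinations(names, 2)]

    # one generous stream of noise factors, consumed in order (redraws included)
    n_draws = 4 * (len(names) + len(pair_plan))
    factors = iter(_lognormal_factors(rng_noise, config.noise_cv, n_draws))

    singles = {
        name: float(_noisy_rate(rate, factors, model.lambda_c))
        for name, rate in true_singles.items()
    }

    pairs = []
    for s1, s2, group in pair_plan:
        r1, r2 = true_singles[s1], true_singles[s2]
        a1 = r1 / (1.0 - r1 / model.lambda_c)
        a2 = r2 / (1.0 - r2 / model.lambda_c)
        if group == "B":
            if r1 <= r2:
                a1 *= config.suppression_factor
            else:
                a2 *= config.suppression_factor
        true_mixed = single_rate_from_capacity(a1 + a2, model)
        assert true_mixed < model.lambda_c
        pairs.append(
            PairObservation(
                substrate_1=s1,
                substrate_2=s2,
                rate=float(_noisy_rate(true_mixed, factors, model.lambda_c)),
                group=group,
            )
        )
    logger.info(
        "synthetic study: seed=%d, %d substrates, %d pairs, lambda_c=%g/h, "
        "noise_cv=%g, suppression=%g",
        config.seed, len(names), len(pairs), config.lambda_c_true,
        config.noise_cv, config.suppression_factor,
    )
    return GrowthTable(singles=singles, pairs=tuple(pairs))


def generate_cline_points(
    n: int,
    lambda_c_true: float = 1.16,
    e0_true: float = 1000.0,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> list[CLinePoint]:
    """Synthetic C-line data: rates uniform on (0.1, 0.95*lambda_c), noisy line.

    Expression is ``e0_true * (1 - rate/lambda_c_true)`` times a unit-mean
    log-normal factor with coefficient of variation ``noise_cv``.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 C-line points, got {n}")
    ss = np.random.SeedSequence(seed)
    rng_rates, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    rates = rng_rates.uniform(0.1, 0.95 * lambda_c_true, size=n)
    noise = _lognormal_factors(rng_noise, noise_cv, n)
    return [
        CLinePoint(
            rate=float(r),
            expression=float(e0_true * (1.0 - r / lambda_c_true) * f),
            condition=f"condition_{i+1}",
        )
        for i, (r, f) in enumerate(zip(rates, noise))
    ]


class LambdaCEstimate(NamedTuple):
    lambda_c_hat: float
    ci_95: tuple[float, float]
    n_pairs: int


def _predict(r1: np.ndarray, r2: np.ndarray, lambda_c: float) -> np.ndarray:
    a1 = r1 / (1.0 - r1 / lambda_c)
    a2 = r2 / (1.0 - r2 / lambda_c)
    s = a1 + a2
    return s / (1.0 + s / lambda_c)


def _sse(lambda_c: float, r1: np.ndarray, r2: np.ndarray, measured: np.ndarray) -> float:
    return float(np.sum((measured - _predict(r1, r2, lambda_c)) ** 2))


def _minimize(r1, r2, measured, lo, hi) -> float:
    res = minimize_scalar(
        _sse, args=(r1, r2, measured), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def recover_lambda_c(
    table: GrowthTable,
    *,
    upper_bound: float = 10.0,
    n_boot: int = 1000,
    seed: int = DEFAULT_RECOVERY_SEED,
) -> LambdaCEstimate:
    """Estimate the speed limit from growth data alone, with a bootstrap CI.

    Minimizes the sum of squared differences between measured group-A mixed
    rates and the composition prediction, over lambda_c in
    ``(max single rate + 1e-6, upper_bound)``, by bounded scalar
    minimization.

    The 95% CI is a parametric bootstrap under the generative measurement
    model: the replicate noise level is estimated from the group-A relative
    residuals (deflated by the model's log-sensitivity to the single rates,
    since measurement error in the singles propagates into the
    predictions), then unit-mean log-normal noise is re-drawn per substrate
    (singles) and per pair (mixed measurements) around the fitted model and
    the estimate recomputed ``n_boot`` times.  Drawing one noise factor per
    *substrate* matters: a substrate's measurement error is shared by every
    pair that contains it, which case resampling of pairs cannot represent
    (case resampling materially under-covers here).

    This estimator is an exploratory alternative to calibrating lambda_c
    from expression data; with only growth rates it is noisier.

    Raises
    ------
    UninformativeDataError
        If the objective is flat across the bracket or minimized at a
        bracket endpoint.
    ValueError
        If fewer than 3 group-A pairs are available.
    """
    group_a = table.group("A")
    if len(group_a) < 3:
        raise ValueError(f"need at least 3 group-A pairs, got {len(group_a)}")
    substrates = sorted(table.singles)
    sub_index = {s: i for i, s in enumerate(substrates)}
    idx1 = np.array([sub_index[p.substrate_1] for p in group_a])
    idx2 = np.array([sub_index[p.substrate_2] for p in group_a])
    singles = np.array([table.singles[s] for s in substrates])
    measured = np.array([p.rate for p in group_a])
    r1, r2 = singles[idx1], singles[idx2]
    lo = float(singles.max()) + 1e-6
    if not lo < upper_bound:
        raise ValueError(f"upper bound {upper_bound} below search floor {lo}")

    grid = np.geomspace(lo * 1.000001, upper_bound, 24)
    grid_vals = np.array([_sse(g, r1, r2, measured) for g in grid])
    scale = max(float(grid_vals.max()), float(np.sum(measured**2)) * 1e-14)
    if float(grid_vals.max() - grid_vals.min()) <= 1e-12 * scale:
        raise UninformativeDataError(
            "objective is numerically flat over the search bracket; the data "
            "do not identify lambda_c"
        )
    estimate = _minimize(r1, r2, measured, lo, upper_bound)
    span = upper_bound - lo
    if estimate - lo < 1e-4 * span or upper_bound - estimate < 1e-4 * span:
        raise UninformativeDataError(
            f"lambda_c minimizer {estimate:.4g}/h lies on the search bound "
            f"({lo:.4g}, {upper_bound:.4g}); the data do not identify lambda_c"
        )

    # noise cv from relative residuals, deflated by singles-error propagation
    predicted = _predict(r1, r2, estimate)
    resid_var = float((measured / predicted - 1.0).var(ddof=1))
    h = 1e-6
    w1 = (np.log(_predict(r1 * (1 + h), r2, estimate)) - np.log(predicted)) / h
    w2 = (np.log(_predict(r1, r2 * (1 + h), estimate)) - np.log(predicted)) / h
    inflation = 1.0 + float(np.mean(w1**2 + w2**2))
    cv2 = max(resid_var / inflation, 0.0)
    sigma = math.sqrt(math.log1p(cv2))
    mu = -sigma * sigma / 2.0

    rng = np.random.default_rng(seed)
    n = len(group_a)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        sub_noise = rng.lognormal(mu, sigma, size=len(substrates))
        pair_noise = rng.lognormal(mu, sigma, size=n)
        singles_b = singles * sub_noise
        boots[b] = _minimize(
            singles_b[idx1], singles_b[idx2], predicted * pair_noise, lo, upper_bound
        )
    ci = tuple(float(v) for v in np.percentile(boots, [2.5, 97.5]))
    logger.info(
        "recover_lambda_c: %d group-A pairs, estimate=%.4f/h, CI95=(%.4f, %.4f), "
        "residual cv=%.3f",
        n, estimate, ci[0], ci[1], math.sqrt(cv2),
    )
    return LambdaCEstimate(lambda_c_hat=estimate, ci_95=ci, n_pairs=n)
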