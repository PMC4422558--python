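"""Estimating the C-line from (growth rate, expression) data.

The C-line is the negative linear relation between catabolic reporter
expression and growth rate.  Its horizontal intercept is the speed-limit
parameter ``lambda_c`` that the composition model needs, so fitting the
line — ordinary least squares of expression on rate, then
``lambda_c = -intercept/slope`` — is the calibration step of the whole
pipeline.  The ratio of two regression coefficients has no exact
finite-sample distribution, so the confidence interval is obtained by
case-resampling bootstrap (Fieller's theorem would be the classical
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CLinePoint",
    "CLineFitResult",
    "NoCLineError",
    "fit_cline",
    "bootstrap_lambda_c_ci",
]

#: Default bootstrap replicate count and seed for reproducible intervals.
DEFAULT_N_BOOT = 10_000
DEFAULT_BOOT_SEED = 20150410


class NoCLineError(ValueError):
    """The fitted slope is non-negative: the data show no C-line behaviour."""


@dataclass(frozen=True)
class CLinePoint:
    """One growth condition: steady-state rate (1/h) and reporter expression.

    ``condition`` names the substrate or substrate pair; it is carried
    through for reporting only.
    """

    rate: float
    expression: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rate) and self.rate >= 0):
            raise ValueError(f"rate must be finite and >= 0, got {self.rate!r}")
        if not (np.isfinite(self.expression) and self.expression >= 0):
            raise ValueError(
                f"expression must be finite and >= 0, got {self.expression!r}"
            )


@dataclass(frozen=True)
class CLineFitResult:
    """OLS fit of expression on growth rate, reported as C-line parameters.

    Attributes
    ----------
    e0 : float
        Vertical intercept — unrepressed expression level.
    lambda_c_hat : float
        Horizontal intercept ``-intercept/slope``, 1/h.
    slope : float
        Raw OLS slope (expression units per 1/h); negative for a C-line.
    r_squared : float
        Coefficient of determination of the linear fit.
    n_points : int
        Number of conditions fitted.
    lambda_c_ci : tuple[float, float] | None
        Bootstrap 95% percentile interval for ``lambda_c_hat``, if computed.
    """

    e0: float
    lambda_c_hat: float
    slope: float
    r_squared: float
    n_points: int
    lambda_c_ci: tuple[float, float] | None = None


def _xy(points: list[CLinePoint]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.rate for p in points], dtype=float)
    y = np.array([p.expression for p in points], dtype=float)
    return x, y


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Return (slope, intercept) of the least-squares line."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    return slope, float(ym - slope * xm)


def fit_cline(points: list[CLinePoint]) -> CLineFitResult:
    """Fit the C-line by OLS and derive its intercepts.

    Requires at least three points spanning at least two distinct growth
    rates.  Raises :class:`NoCLineError` when the fitted slope is not
    negative — expression that does not fall with growth rate carries no
    information about ``lambda_c``.
    """
    if len(points) < 3:
        raise ValueError(f"need at least 3 points to fit a C-line, got {len(points)}")
    x, y = _xy(points)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct growth rates to fit a C-line")
    slope, intercept = _ols_line(x, y)
    if slope >= 0:
        raise NoCLineError(
            f"fitted slope {slope:.4g} >= 0: no C-line behaviour in these data"
        )
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CLineFitResult(
        e0=intercept,
        lambda_c_hat=-intercept / slope,
        slope=slope,
        r_squared=r2,
        n_points=len(points),
    )


def bootstrap_lambda_c_ci(
    points: list[CLinePoint],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> tuple[float, float]:
    """Case-resampling bootstrap 95% interval for the horizontal intercept.

    Conditions are resampled with replacement ``n_boot`` times and the line
    refitted; the 2.5–97.5 percentile interval of ``-intercept/slope`` over
    the replicates is returned.  Replicates with a non-negative slope or
    with no rate variation carry no horizontal intercept and are discarded;
    more than 50% discards raises, since the interval would then be
    meaningless.  Deterministic for a given seed.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    fit_cline(points)  # validates that a C-line fit exists
    x, y = _xy(points)
    n = x.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    sxx = np.sum((xb - xm) ** 2, axis=1)
    sxy = np.sum((xb - xm) * (yb - ym), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope_b = sxy / sxx
        intercept_b = ym[:, 0] - slope_b * xm[:, 0]
        lam_b = -intercept_b / slope_b
    valid = (sxx > 0) & (slope_b < 0)
    n_discard = int(n_boot - valid.sum())
    if n_discard > n_boot // 2:
        raise RuntimeError(
            f"{n_discard}/{n_boot} bootstrap replicates had no C-line "
            "(slope >= 0 or degenerate rates); interval not reliable"
        )
    lo, hi = np.percentile(lam_b[valid], [2.5, 97.5])
    return float(lo), float(hi)


def fit_cline_with_ci(
    points: list[CLinePoint],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> CLineFitResult:
    """Convenience: :func:`fit_cline` with the bootstrap interval attached."""
    result = fit_cline(points)
    return replace(result, lambda_c_ci=bootstrap_lambda_c_ci(points, n_boot, seed))
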