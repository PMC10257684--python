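"""Percolation-theory predictions of water-patch number and size.

The water-patch size distribution follows ``n(s) = s^-tau exp(-s/xi)``
with Fisher exponent ``tau`` and saturation-dependent cutoff
``xi = gamma (1 - theta)``. The characteristic patch count in a domain
of scale L is

    Nc(theta) = N0(theta) (1/xi)^(tau-1) Gamma(1-tau) - E_tau(1/xi),

with finite-size normalization ``N0 = (L / lambda_c)^(d (1 - theta))``,
``Gamma`` the (complete) gamma function and ``E_tau`` the generalized
exponential integral, both evaluated by analytic continuation for the
non-integer, negative arguments that tau > 1 produces. Mass
conservation fixes the characteristic patch size ``Sc = theta / Nc``.

At full saturation the formula does not tend to a finite limit; the
single-cluster convention Nc(1) = 1 is applied there, and Nc is clamped
to >= 1 elsewhere (a patch count below one patch is meaningless).

Note on the defining integral: Nc is nominally the zeroth moment
``int_0^1 n(s) ds``, which diverges at s -> 0 for tau > 1. The
analytically continued value of that integral (the full bracket
``x^(tau-1) [Gamma(1-tau) - Gamma(1-tau, x)]``) is exposed as
:func:`bracket_continuation` together with a lower-cutoff quadrature
diagnostic, but it is *negative* over most of the saturation range and
is therefore not used for the patch count itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

#: 2D Fisher exponent, 187/91 (used at the pore scale)
FISHER_TAU_2D = 187.0 / 91.0
#: 3D Fisher exponent (used for field-scale upscaling)
FISHER_TAU_3D = 2.19


@dataclass
class PatchTheoryParams:
    """Parameters of the patch-statistics model."""

    tau: float = FISHER_TAU_2D
    gamma: float = 100.0
    L: float = 0.03  # domain length scale [m]
    lambda_c: float = 1e-3  # grain size [m]
    d: int = 2

    def __post_init__(self) -> None:
        if not 1.0 < self.tau < 3.0:
            raise ValueError("tau must lie in (1, 3)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.L <= self.lambda_c:
            raise ValueError("L must exceed lambda_c")
        if self.d not in (2, 3):
            raise ValueError("d must be 2 or 3")


@dataclass
class PatchPrediction:
    saturation: float
    xi: float
    n0: float
    nc: float
    sc: float
    clamped: bool = False


def upper_gamma_cont(a: float, x: float) -> float:
    """Upper incomplete gamma Gamma(a, x) for real a (x > 0).

    For a <= 0 the recurrence Gamma(a, x) = (Gamma(a+1, x) - x^a e^-x)/a
    is applied until the argument is positive, then scipy's regularized
    gammaincc is used. The integral is positive for all x > 0.
    """
    sign, logv = log_upper_gamma_cont(a, x)
    return sign * np.exp(logv)


def log_upper_gamma_cont(a: float, x: float) -> tuple[float, float]:
    """(sign, log|Gamma(a, x)|) for real a and x > 0, safe for large x."""
    if x <= 0:
        raise ValueError("x must be positive")
    if x > 700.0:
        # asymptotic expansion: Gamma(a,x) ~ x^(a-1) e^-x (1 + (a-1)/x + ...)
        corr = 1.0 + (a - 1.0) / x + (a - 1.0) * (a - 2.0) / x**2
        return 1.0, (a - 1.0) * np.log(x) - x + np.log(corr)
    val = _upper_gamma_value(a, x)
    if val <= 0.0:  # rounding in the recurrence; the true value is positive
        return 1.0, -np.inf
    return 1.0, float(np.log(val))


def _upper_gamma_value(a: float, x: float) -> float:
    n = 0
    while a + n <= 0:
        n += 1
    # Gamma(a+n, x) with positive argument
    g = special.gammaincc(a + n, x) * special.gamma(a + n)
    for k in range(n, 0, -1):
        ak = a + k - 1
        g = (g - x**ak * np.exp(-x)) / ak
    return float(g)


def exp_integral_tau(tau: float, x: float) -> float:
    """Generalized exponential integral E_tau(x) = x^(tau-1) Gamma(1-tau, x)."""
    sign, logv = log_upper_gamma_cont(1.0 - tau, x)
    return sign * np.exp((tau - 1.0) * np.log(x) + logv)


def bracket_continuation(tau: float, x: float) -> float:
    """Analytic continuation of int_0^1 s^-tau exp(-x s) ds.

    Equals x^(tau-1) [Gamma(1-tau) - Gamma(1-tau, x)], i.e. the full
    bracket of the patch-count formula. Negative for small x when
    tau > 1 (the finite part subtracts the divergent boundary term).
    """
    if x <= 0:
        raise ValueError("x must be positive")
    return float(
        x ** (tau - 1.0) * special.gamma(1.0 - tau) - exp_integral_tau(tau, x)
    )


def nc_integral_cutoff(
    tau: float, xi: float, s_min: float, s_max: float = 1.0
) -> float:
    """Lower-cutoff quadrature diagnostic: int_{s_min}^{s_max} s^-tau e^(-s/xi) ds."""
    if s_min <= 0:
        raise ValueError("s_min must be positive")
    val, _ = integrate.quad(
        lambda s: s ** (-tau) * np.exp(-s / xi), s_min, s_max, limit=200
    )
    return float(val)


def patch_size_density(s: np.ndarray | float, tau: float, xi: float) -> np.ndarray | float:
    """Unnormalized patch-size density n(s) = s^-tau exp(-s/xi)."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr <= 0):
        raise ValueError("s must be positive")
    if xi <= 0:
        raise ValueError("xi must be positive")
    out = s_arr ** (-tau) * np.exp(-s_arr / xi)
    return out if out.ndim else float(out)


def patch_size_density_normalized(
    s: np.ndarray | float, tau: float, xi: float, s_min: float, s_max: float = 1.0
) -> np.ndarray | float:
    """n(s) normalized to integrate to 1 on [s_min, s_max]."""
    z = xi ** (1.0 - tau) * (
        upper_gamma_cont(1.0 - tau, s_min / xi) - upper_gamma_cont(1.0 - tau, s_max / xi)
    )
    return patch_size_density(s, tau, xi) / z


def predict_patches(theta: float, params: PatchTheoryParams) -> PatchPrediction:
    """Predict patch count Nc and characteristic size Sc at saturation theta.

    Applies the closed-form patch-count model with the saturated-limit
    convention Nc(1) = 1 and clamping Nc >= 1 elsewhere; Sc = theta / Nc
    always (mass conservation).
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("saturation must lie in (0, 1]")
    if theta == 1.0:
        return PatchPrediction(saturation=1.0, xi=0.0, n0=1.0, nc=1.0, sc=1.0)
    xi = params.gamma * (1.0 - theta)
    x = 1.0 / xi
    n0 = (params.L / params.lambda_c) ** (params.d * (1.0 - theta))
    nc_raw = n0 * x ** (params.tau - 1.0) * special.gamma(
        1.0 - params.tau
    ) - exp_integral_tau(params.tau, x)
    clamped = nc_raw < 1.0
    nc = max(nc_raw, 1.0)
    return PatchPrediction(
        saturation=theta, xi=xi, n0=n0, nc=float(nc), sc=theta / float(nc), clamped=bool(clamped)
    )


def prediction_table(
    thetas: np.ndarray, params: PatchTheoryParams
) -> "np.recarray":
    """Tabulate (theta, xi, N0, Nc, Sc) predictions, e.g. for CSV export."""
    import pandas as pd

    rows = [predict_patches(float(t), params) for t in thetas]
    return pd.DataFrame(
        {
            "theta": [r.saturation for r in rows],
            "xi": [r.xi for r in rows],
            "n0": [r.n0 for r in rows],
            "nc": [r.nc for r in rows],
            "sc": [r.sc for r in rows],
        }
    )
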