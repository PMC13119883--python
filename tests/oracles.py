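"""Independent brute-force oracles for the regression-based measures.

Deliberately written from first principles (2x2 normal equations solved by
Cramer's rule; a hand-coded IRLS loop for the logistic fit) so they share no
code path with the package's fitting routines.
"""

from __future__ import annotations

import math
from typing import Sequence


def _solve_2x2(a11, a12, a21, a22, b1, b2):
    det = a11 * a22 - a12 * a21
    if det == 0:
        raise ZeroDivisionError("singular normal equations")
    return (b1 * a22 - b2 * a12) / det, (a11 * b2 - a21 * b1) / det


def weighted_linear_fit(
    x: Sequence[float], y: Sequence[float], w: Sequence[float]
) -> tuple[float, float]:
    """(intercept, slope) minimizing sum w_i (y_i - a - b x_i)^2."""
    sw = sum(w)
    swx = sum(wi * xi for wi, xi in zip(w, x))
    swxx = sum(wi * xi * xi for wi, xi in zip(w, x))
    swy = sum(wi * yi for wi, yi in zip(w, y))
    swxy = sum(wi * xi * yi for wi, xi, yi in zip(w, x, y))
    return _solve_2x2(sw, swx, swx, swxx, swy, swxy)


def sii_rii_linear(
    ranks: Sequence[float], estimates: Sequence[float], weights: Sequence[float]
) -> tuple[float, float]:
    """SII (pp) and RII from the linear-link weighted fit."""
    a, b = weighted_linear_fit(ranks, estimates, weights)
    p0, p1 = a, a + b
    return p1 - p0, p1 / p0


def weighted_logit_fit(
    x: Sequence[float],
    p: Sequence[float],
    w: Sequence[float],
    tol: float = 1e-14,
    maxiter: int = 500,
) -> tuple[float, float]:
    """(intercept, slope) of the weighted logistic fit to proportions.

    Solves the score equations sum_i w_i (p_i - mu_i) [1, x_i] = 0,
    mu_i = expit(a + b x_i), by iteratively reweighted least squares with
    working weights w_i mu_i (1 - mu_i).
    """
    pbar = sum(wi * pi for wi, pi in zip(w, p)) / sum(w)
    a, b = math.log(pbar / (1 - pbar)), 0.0
    for _ in range(maxiter):
        mu = [1.0 / (1.0 + math.exp(-(a + b * xi))) for xi in x]
        v = [mi * (1.0 - mi) for mi in mu]
        z = [
            (a + b * xi) + (pi - mi) / vi
            for xi, pi, mi, vi in zip(x, p, mu, v)
        ]
        ww = [wi * vi for wi, vi in zip(w, v)]
        a_new, b_new = weighted_linear_fit(x, z, ww)
        if abs(a_new - a) < tol and abs(b_new - b) < tol:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    return a, b


def sii_rii_logit(
    ranks: Sequence[float],
    estimates: Sequence[float],
    weights: Sequence[float],
    clip: tuple[float, float] = (0.01, 99.99),
) -> tuple[float, float]:
    """SII (pp) and RII from the logit-link weighted fit on percentages."""
    p = [min(max(e, clip[0]), clip[1]) / 100.0 for e in estimates]
    a, b = weighted_logit_fit(ranks, p, weights)
    mu0 = 100.0 / (1.0 + math.exp(-a))
    mu1 = 100.0 / (1.0 + math.exp(-(a + b)))
    return mu1 - mu0, mu1 / mu0


def median_ci_ranks(n: int, level: float = 0.95) -> tuple[int, int]:
    """Tightest pair of 1-based order-statistic ranks covering the median.

    Brute-force enumeration of the Binomial(n, 1/2) pmf, no scipy.
    """
    pmf = [math.comb(n, k) / 2.0**n for k in range(n + 1)]
    best = None
    for lo in range(1, n + 1):
        for hi in range(lo + 1, n + 1):
            cover = sum(pmf[lo:hi])  # P(lo <= B <= hi - 1)
            if cover >= level:
                key = (hi - lo, abs((lo - 1) - (n - hi)), lo, hi)
                if best is None or key < best:
                    best = key
                break
    if best is None:
        raise ValueError(f"no pair reaches level {level} for n={n}")
    return best[2], best[3]
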