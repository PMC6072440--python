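"""Small reusable statistics: Storey's pi1, G-tests, 2x2 enrichment."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class PiOneEstimate:
    pi1: float
    pi0: float
    method: str
    n: int
    lambda_grid: np.ndarray


def storey_pi1(p_values: np.ndarray,
               lambda_grid: np.ndarray | None = None) -> PiOneEstimate:
    """Estimate the alternative fraction pi1 = 1 - pi0 from a p-value set.

    pi0(lambda) = #{p > lambda} / (n * (1 - lambda)) over the grid; the final
    pi0 is a cubic smoothing spline through the grid evaluated at the largest
    lambda, clipped to [0, 1].  Degenerate p distributions fall back to the
    fixed lambda = 0.5 estimator with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    n = len(p)
    if n < 20:
        raise ValueError("need at least 20 p-values")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_lam = np.array([np.mean(p > L) / (1 - L) for L in lam])
    try:
        spline = interpolate.make_smoothing_spline(lam, pi0_lam)
        pi0 = float(spline(lam[-1]))
        method = "smoother"
    except Exception:  # pragma: no cover - degenerate grids
        pi0 = np.nan
        method = "fallback"
    if not np.isfinite(pi0):
        logger.warning("spline smoothing failed; using fixed lambda=0.5")
        pi0 = float(np.mean(p > 0.5) / 0.5)
        method = "fixed-0.5"
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return PiOneEstimate(1.0 - pi0, pi0, method, n, lam)


def g_test(table: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio (G) test of independence on a 2x2 table.

    G = 2 * sum O * ln(O/E) with the 0 * ln 0 = 0 convention; p from
    chi-square with 1 df.  A zero row or column gives G = 0, p = 1.
    """
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2) or (O < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    if (O.sum(axis=0) == 0).any() or (O.sum(axis=1) == 0).any():
        return 0.0, 1.0
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    G = float(2.0 * terms.sum())
    G = max(G, 0.0)
    return G, float(sps.chi2.sf(G, df=1))


def fisher_enrichment(table: np.ndarray) -> tuple[float, float]:
    """Sample odds ratio and two-sided hypergeometric (Fisher) p for a 2x2
    table.  OR = ad/bc, infinite when bc = 0 with ad > 0."""
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2) or (O < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    a, b, c, d = O.ravel()
    if b * c == 0:
        oddsratio = np.inf if a * d > 0 else np.nan
    else:
        oddsratio = (a * d) / (b * c)
    _, p = sps.fisher_exact(O.astype(np.int64), alternative="two-sided")
    return float(oddsratio), float(p)
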