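"""Kinship construction, REML variance components, and LOCO residualization.

The single-component model ``y = a + e`` with ``a ~ N(0, s2_A * A)`` and
``e ~ N(0, s2_E * I)`` is fit by restricted maximum likelihood using a
spectral decomposition of the kinship matrix, so each additional phenotype
costs only a rotation and a one-dimensional optimization over the variance
ratio.  The two-component model adds an epistatic kernel (the Hadamard square
``A o A``) and is maximized directly over the 2-simplex of variance fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

_PSD_TOL = 1e-8


@dataclass
class KinshipMatrix:
    """Additive relatedness with optional epistatic (Hadamard-square) kernel."""

    A: np.ndarray
    AA: np.ndarray | None = None
    n_markers: int = 0
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        self.A = A

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (values ascending, PSD-checked)."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.A)
            if vals[0] < -_PSD_TOL * max(1.0, vals[-1]):
                raise ValueError("kinship matrix is not positive semidefinite")
            self._eig = (np.maximum(vals, 0.0), vecs)
        return self._eig


@dataclass
class VarianceComponents:
    sigma2_A: float
    sigma2_E: float
    sigma2_AA: float | None
    h2: float
    loglik: float
    converged: bool

    @property
    def total(self) -> float:
        return self.sigma2_A + self.sigma2_E + (self.sigma2_AA or 0.0)


def additive_kinship(genotypes, exclude_chromosome: str | None = None,
                     with_epistatic: bool = False) -> KinshipMatrix:
    """A = Gc Gc' / c from column-centered genotypes, scaled to mean diag 1.

    ``exclude_chromosome`` drops that chromosome's markers before centering
    (the LOCO kinship used during mapping).  ``with_epistatic`` also stores
    the entry-wise square A o A.
    """
    G = genotypes.values
    if exclude_chromosome is not None:
        keep = (genotypes.marker_map["chrom"] != exclude_chromosome).to_numpy()
        G = G[:, keep]
    if G.shape[1] < 2:
        raise ValueError("fewer than 2 markers after chromosome exclusion")
    Gc = G - G.mean(axis=0)
    A = Gc @ Gc.T
    c = np.trace(A) / A.shape[0]
    if c == 0:
        raise ValueError("all markers constant; kinship undefined")
    A /= c
    AA = A * A if with_epistatic else None
    return KinshipMatrix(A, AA, n_markers=G.shape[1])


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _reml_loglik_rotated(log_delta: float, lam: np.ndarray, yt: np.ndarray,
                         Xt: np.ndarray) -> float:
    """Restricted log-likelihood at variance ratio delta = s2_E / s2_A.

    Operates in the eigenbasis of A, where the covariance is
    s2_A * diag(lam + delta).  Fixed effects ``Xt`` are profiled by GLS and
    s2_A is profiled analytically.
    """
    delta = np.exp(log_delta)
    d = lam + delta
    q = Xt.shape[1]
    n = len(yt)
    w = 1.0 / d
    XtWX = (Xt * w[:, None]).T @ Xt
    XtWy = (Xt * w[:, None]).T @ yt
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf
    r = yt - Xt @ beta
    rss = float(r @ (w * r))
    if rss <= 0:
        return -np.inf
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    nq = n - q
    return -0.5 * (nq * np.log(2 * np.pi * rss / nq) + nq
                   + np.sum(np.log(d)) + logdet_XtWX)


def fit_mixed(y: np.ndarray, K: KinshipMatrix, components: str = "A",
              X: np.ndarray | None = None, n_grid: int = 101,
              tol: float = 1e-6) -> VarianceComponents:
    """REML variance components for one phenotype.

    ``components="A"`` fits the single additive kernel via spectral
    decomposition and a log-spaced grid over delta = s2_E/s2_A refined by
    bounded scalar optimization.  ``components="A,AA"`` additionally fits the
    Hadamard-square kernel by Nelder-Mead over the simplex of variance
    fractions (5 starts).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    n = len(y)
    if K.n != n:
        raise ValueError("kinship dimension does not match phenotype")
    if X is None:
        X = np.ones((n, 1))
    if components == "A":
        return _fit_single(y, K, X, n_grid, tol)
    if components in ("A,AA", "AA"):
        if K.AA is None:
            raise ValueError("kinship has no epistatic kernel; build with with_epistatic=True")
        return _fit_two(y, K, X)
    raise ValueError(f"unknown component set {components!r}")


def _fit_single(y, K, X, n_grid, tol) -> VarianceComponents:
    lam, U = K.eig()
    yt = U.T @ y
    Xt = U.T @ X
    grid = np.linspace(np.log(1e-6), np.log(1e6), n_grid)
    vals = np.array([_reml_loglik_rotated(ld, lam, yt, Xt) for ld in grid])
    best = int(np.argmax(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda ld: -_reml_loglik_rotated(ld, lam, yt, Xt),
        bounds=(lo, hi), method="bounded", options={"xatol": tol})
    converged = bool(res.success)
    log_delta = float(res.x) if res.fun < -vals[best] else grid[best]
    loglik = _reml_loglik_rotated(log_delta, lam, yt, Xt)
    delta = np.exp(log_delta)
    d = lam + delta
    w = 1.0 / d
    XtWX = (Xt * w[:, None]).T @ Xt
    beta = np.linalg.solve(XtWX, (Xt * w[:, None]).T @ yt)
    r = yt - Xt @ beta
    nq = len(y) - X.shape[1]
    s2a = float(r @ (w * r)) / nq
    s2e = s2a * delta
    h2 = s2a / (s2a + s2e) if (s2a + s2e) > 0 else 0.0
    # treat the grid edges as boundary estimates (h2 -> 0 or 1)
    if log_delta >= np.log(1e6) - 1e-9:
        h2, s2a, s2e = 0.0, 0.0, float(np.var(y, ddof=1))
    return VarianceComponents(s2a, s2e, None, float(np.clip(h2, 0, 1)),
                              float(loglik), converged)


def _profiled_reml_general(V_unit: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    """REML log-likelihood with total variance profiled out of V = s2 * V_unit."""
    n, q = X.shape
    try:
        L = np.linalg.cholesky(V_unit)
    except np.linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = np.linalg.solve(V_unit, y)
    Vi_X = np.linalg.solve(V_unit, X)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    ypy = float(r @ np.linalg.solve(V_unit, r))
    if ypy <= 0:
        return -np.inf
    nq = n - q
    return -0.5 * (nq * np.log(2 * np.pi * ypy / nq) + nq + logdetV + logdet_XtViX)


def _fit_two(y, K, X) -> VarianceComponents:
    n, q = X.shape

    def objective(z):
        # softmax-free simplex parameterization: clip to the open simplex
        fa, faa = z
        if fa < 0 or faa < 0 or fa + faa > 0.9999:
            return np.inf
        V = fa * K.A + faa * K.AA + (1 - fa - faa) * np.eye(n)
        return -_profiled_reml_general(V, y, X)

    starts = [(0.25, 0.05), (0.5, 0.1), (0.1, 0.3), (0.05, 0.05), (0.4, 0.3)]
    best = None
    for s in starts:
        res = optimize.minimize(objective, s, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    fa, faa = np.clip(best.x, 0, 1)
    tot = fa + faa
    if tot > 0.9999:
        fa, faa = fa / tot * 0.9999, faa / tot * 0.9999
    V = fa * K.A + faa * K.AA + (1 - fa - faa) * np.eye(n)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    r = y - X @ beta
    s2_tot = float(r @ np.linalg.solve(V, r)) / (n - q)
    s2a, s2aa = s2_tot * fa, s2_tot * faa
    s2e = s2_tot * (1 - fa - faa)
    h2 = s2a / (s2a + s2aa + s2e) if s2_tot > 0 else 0.0
    return VarianceComponents(s2a, s2e, s2aa, float(np.clip(h2, 0, 1)),
                              float(-best.fun), bool(best.success))


def loco_residual(y: np.ndarray, genotypes, chromosome: str,
                  fixed_design: np.ndarray | None = None,
                  fixed_markers: np.ndarray | None = None,
                  kinship: KinshipMatrix | None = None) -> np.ndarray:
    """Residualize a phenotype on everything *except* the focal chromosome.

    Fits ``y = W b + a_L + e`` where ``W`` stacks the covariate design and any
    off-chromosome background markers (``fixed_markers``), and ``a_L`` is the
    polygenic effect under the leave-one-chromosome-out kinship.  Returns
    ``y - W b_hat - BLUP(a_L)``: on-chromosome signal is retained because the
    focal chromosome contributes to neither the fixed nor the random part.

    A precomputed LOCO ``kinship`` may be supplied to share the spectral
    decomposition across genes.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    parts = [np.ones((n, 1))]
    if fixed_design is not None:
        parts.append(np.atleast_2d(np.asarray(fixed_design, dtype=float)))
    if fixed_markers is not None and np.size(fixed_markers):
        parts.append(np.atleast_2d(np.asarray(fixed_markers, dtype=float)))
    W = np.column_stack(parts)
    if kinship is None:
        kinship = additive_kinship(genotypes, exclude_chromosome=chromosome)
    lam, U = kinship.eig()
    yt = U.T @ y
    Wt = U.T @ W
    delta, beta = _fit_single_rotated(lam, yt, Wt)
    resid_fixed = y - W @ beta
    shrink = lam / (lam + delta)
    blup = U @ (shrink * (U.T @ resid_fixed))
    return resid_fixed - blup


def _fit_single_rotated(lam, yt, Wt, n_grid: int = 51) -> tuple[float, np.ndarray]:
    """Grid+refine REML in an already-rotated basis; returns (delta, beta_GLS)."""
    grid = np.linspace(np.log(1e-6), np.log(1e6), n_grid)
    vals = np.array([_reml_loglik_rotated(ld, lam, yt, Wt) for ld in grid])
    best = int(np.argmax(vals))
    lo, hi = grid[max(best - 1, 0)], grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda ld: -_reml_loglik_rotated(ld, lam, yt, Wt),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-5})
    log_delta = float(res.x) if -res.fun >= vals[best] else float(grid[best])
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    XtWX = (Wt * w[:, None]).T @ Wt
    beta = np.linalg.lstsq(XtWX, (Wt * w[:, None]).T @ yt, rcond=None)[0]
    return delta, beta


def save_kinship(K: KinshipMatrix, path: str) -> None:
    """Cache a kinship matrix (and its epistatic kernel) to HDF5."""
    import h5py
    with h5py.File(path, "w") as fh:
        fh.create_dataset("A", data=K.A)
        if K.AA is not None:
            fh.create_dataset("AA", data=K.AA)
        fh.attrs["n_markers"] = K.n_markers


def load_kinship(path: str) -> KinshipMatrix:
    import h5py
    with h5py.File(path, "r") as fh:
        A = fh["A"][...]
        AA = fh["AA"][...] if "AA" in fh else None
        return KinshipMatrix(A, AA, n_markers=int(fh.attrs.get("n_markers", 0)))


def epistatic_share_summary(fits: list[VarianceComponents]) -> float:
    """Across-gene ratio of the average A o A component to the average A
    component (sensitive to outliers by construction; reported for parity)."""
    a = np.mean([f.sigma2_A for f in fits])
    aa = np.mean([f.sigma2_AA or 0.0 for f in fits])
    return float(aa / a) if a > 0 else np.nan
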