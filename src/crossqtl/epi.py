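"""eQTL-eQTL interaction detection.

Three scans over additive-model residuals: a full two-dimensional scan of all
admissible marker pairs, a marginal scan restricted to pairs where one member
has a significant additive effect, and a targeted additive-pair F-test
between a gene's detected eQTL peaks.  The interaction statistic is the LOD
of the product term over the marginal two-marker model,
``(n/2) * log10(RSS_additive / RSS_full)``, so purely additive signal cannot
masquerade as interaction.  Same-chromosome pairs closer than 20 collapsed
markers are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeMatrix, residualize
from .mixed import KinshipMatrix, _fit_single_rotated, additive_kinship

LN10 = np.log(10.0)


@dataclass
class InteractionRecord:
    gene: str
    marker1: int          # column index in the (reduced) marker matrix
    marker2: int          # marker1 < marker2 in genome order
    statistic: float      # interaction LOD, or F for the additive-pair test
    var_expl: float
    scan_type: str        # "full" | "marginal" | "additive-pair"


def reduce_markers(genotypes: GenotypeMatrix, cutoff: float = 0.99) -> np.ndarray:
    """Greedy high-correlation marker elimination (findCorrelation-style).

    While any pair exceeds ``|r| > cutoff``, the member of the worst pair with
    the larger mean absolute correlation to the remaining markers is removed
    (ties remove the leftmost).  Returns retained column indices.
    """
    G = genotypes.values
    p = G.shape[1]
    if p < 2:
        return np.arange(p)
    C = np.abs(np.corrcoef(G, rowvar=False))
    np.fill_diagonal(C, 0.0)
    keep = np.ones(p, dtype=bool)
    while True:
        sub = np.where(keep)[0]
        Cs = C[np.ix_(sub, sub)]
        if Cs.size == 0 or Cs.max() <= cutoff:
            break
        i, j = np.unravel_index(np.argmax(Cs), Cs.shape)
        mi, mj = Cs[i].mean(), Cs[j].mean()
        if mi > mj:
            drop = sub[i]
        elif mj > mi:
            drop = sub[j]
        else:
            drop = sub[min(i, j)]
        keep[drop] = False
    return np.where(keep)[0]


def interaction_residual(Y: np.ndarray, design: np.ndarray,
                         eqtl_cols: dict[int, list[int]],
                         genotypes: GenotypeMatrix,
                         kinship: KinshipMatrix | None = None,
                         use_polygenic: bool = True) -> np.ndarray:
    """Residualize each gene on covariates, its significant additive eQTLs and
    the whole-genome polygenic BLUP; these residuals feed the pair scans."""
    n, g = Y.shape
    if use_polygenic and kinship is None:
        kinship = additive_kinship(genotypes)
    R = np.empty_like(Y)
    if use_polygenic:
        lam, U = kinship.eig()
        Dt = U.T @ design
    for gi in range(g):
        cols = eqtl_cols.get(gi, [])
        W = (np.column_stack([design, genotypes.values[:, cols]])
             if cols else design)
        if not use_polygenic:
            R[:, gi] = residualize(Y[:, gi], W)
            continue
        Wt = np.column_stack([Dt, U.T @ genotypes.values[:, cols]]) if cols else Dt
        delta, beta = _fit_single_rotated(lam, U.T @ Y[:, gi], Wt)
        rf = Y[:, gi] - W @ beta
        R[:, gi] = rf - U @ ((lam / (lam + delta)) * (U.T @ rf))
    return R


def _admissible_mask(marker_map: pd.DataFrame, cols: np.ndarray,
                     exclusion: int = 20) -> np.ndarray:
    """Boolean (p, p) mask of testable pairs: upper triangle, excluding
    same-chromosome pairs within ``exclusion`` marker indices."""
    chrom = marker_map["chrom"].to_numpy()[cols]
    idx = np.arange(len(cols))
    same = chrom[:, None] == chrom[None, :]
    close = np.abs(idx[:, None] - idx[None, :]) <= exclusion
    mask = np.triu(np.ones((len(cols), len(cols)), dtype=bool), k=1)
    mask &= ~(same & close)
    return mask


def pair_lod_matrix(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Interaction LOD for every marker pair of one gene's residual.

    Computes RSS of {1, x1, x2} and {1, x1, x2, x1*x2} in closed form from
    genome-wide cross-products (genotypes are exactly +/-1, so all product
    moments reduce to first and second moments of the marker matrix).
    """
    n, p = X.shape
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    G = X.T @ X                    # x_i' x_j
    sx = X.sum(axis=0)             # 1' x_i
    c = X.T @ yc                   # x_i' yc
    M = X.T @ (X * yc[:, None])    # yc' (x_i o x_j)
    sy2 = float(yc @ yc)
    lod = np.zeros((p, p))
    # Normal equations for centered predictors {x1, x2} and {x1, x2, x12}.
    # With +/-1 coding: x12 = x1*x2, x12'x12 = n, x1'x12 = sum(x2), etc.
    for i in range(p):
        xi = X[:, i]
        # vectorized over j > i
        j = np.arange(i + 1, p)
        if len(j) == 0:
            continue
        g12 = G[i, j] - sx[i] * sx[j] / n              # centered x1'x2
        g11 = G[i, i] - sx[i] ** 2 / n
        g22 = G[j, j] - sx[j] ** 2 / n
        c1 = c[i]
        c2 = c[j]
        det_add = g11 * g22 - g12 ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            rss_add = sy2 - (g22 * c1 ** 2 - 2 * g12 * c1 * c2
                             + g11 * c2 ** 2) / det_add
        rss_add = np.where(det_add <= 1e-12, sy2, rss_add)
        # full model adds the centered product term
        s12 = G[i, j]                                   # 1'(x1*x2)
        p1 = sx[j] - sx[i] * s12 / n                    # centered x1'x12
        p2 = sx[i] - sx[j] * s12 / n
        pp = n - s12 ** 2 / n
        cp = M[i, j]                                    # yc'(x1*x2), yc centered
        nk = len(j)
        A = np.empty((nk, 3, 3))
        A[:, 0, 0] = g11
        A[:, 0, 1] = A[:, 1, 0] = g12
        A[:, 0, 2] = A[:, 2, 0] = p1
        A[:, 1, 1] = g22
        A[:, 1, 2] = A[:, 2, 1] = p2
        A[:, 2, 2] = pp
        b = np.stack([np.full(nk, c1), c2, cp], axis=1)
        detA = np.linalg.det(A)
        ok = np.abs(detA) > 1e-10
        rss_full = rss_add.copy()
        if ok.any():
            sol = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
            rss_full[ok] = sy2 - np.einsum("kj,kj->k", b[ok], sol)
        rss_full = np.clip(rss_full, 1e-12, None)
        ratio = np.clip(rss_add, 1e-12, None) / rss_full
        lod[i, j] = (n / 2.0) * np.log10(np.clip(ratio, 1.0, None))
    return lod


def extract_pair_peaks(lod: np.ndarray, mask: np.ndarray,
                       threshold: float, radius: int = 20
                       ) -> list[tuple[int, int, float]]:
    """Greedy max-and-mask 2-D peak extraction above ``threshold``; each peak
    masks ``radius`` markers in both coordinates (and the mirrored block)."""
    work = np.where(mask, lod, -np.inf)
    peaks = []
    while True:
        i, j = np.unravel_index(np.argmax(work), work.shape)
        if not np.isfinite(work[i, j]) or work[i, j] <= threshold:
            break
        peaks.append((int(i), int(j), float(work[i, j])))
        ilo, ihi = max(0, i - radius), i + radius + 1
        jlo, jhi = max(0, j - radius), j + radius + 1
        work[ilo:ihi, jlo:jhi] = -np.inf
        work[jlo:jhi, ilo:ihi] = -np.inf
    return peaks


def scan_pairs(R: np.ndarray, genotypes: GenotypeMatrix, cols: np.ndarray,
               genes: list[str] | None = None, exclusion: int = 20,
               working_threshold: float = 3.0) -> pd.DataFrame:
    """Full 2-D interaction scan for every gene; returns all peaks above the
    working threshold (final significance comes from :func:`pair_fdr`)."""
    X = genotypes.values[:, cols]
    mask = _admissible_mask(genotypes.marker_map, cols, exclusion)
    genes = genes or [f"g{i}" for i in range(R.shape[1])]
    rows = []
    for gi in range(R.shape[1]):
        lod = pair_lod_matrix(R[:, gi], X)
        for i, j, val in extract_pair_peaks(lod, mask, working_threshold,
                                            radius=exclusion):
            rows.append((genes[gi], int(cols[i]), int(cols[j]), val))
    return pd.DataFrame(rows, columns=["gene", "marker1", "marker2", "lod"])


def pair_fdr(observed: pd.DataFrame, permuted: list[pd.DataFrame],
             alpha: float = 0.10, grid: np.ndarray | None = None,
             additive_cols: dict[str, set[int]] | None = None
             ) -> tuple[float | None, pd.DataFrame]:
    """Permutation FDR over pair-scan peaks.

    FDR(T) = mean permuted peak count above T / observed count above T;
    returns the smallest grid threshold under ``alpha`` plus the significant
    observed peaks.  ``additive_cols`` (gene -> marker columns with a
    significant additive effect) switches to the marginal-scan variant, which
    restricts both observed and permuted peaks to pairs touching an additive
    marker of some gene.
    """
    if grid is None:
        grid = np.arange(3.0, 12.01, 0.05)

    def _restrict(df: pd.DataFrame) -> pd.DataFrame:
        if additive_cols is None or df.empty:
            return df
        keep = [
            (row.marker1 in additive_cols.get(row.gene, set()))
            or (row.marker2 in additive_cols.get(row.gene, set()))
            for row in df.itertuples()]
        return df[np.asarray(keep, dtype=bool)]

    obs = _restrict(observed)
    perms = [_restrict(p) for p in permuted]
    if obs.empty:
        return None, obs
    for T in grid:
        n_obs = int((obs["lod"] > T).sum())
        if n_obs == 0:
            continue
        n_exp = float(np.mean([(p["lod"] > T).sum() for p in perms]))
        if n_exp / n_obs < alpha:
            return float(T), obs[obs["lod"] > T].reset_index(drop=True)
    return None, obs.iloc[0:0]


def additive_pair_test(R: np.ndarray, genotypes: GenotypeMatrix,
                       peaks_per_gene: dict[int, list[int]],
                       genes: list[str] | None = None) -> pd.DataFrame:
    """F-test of the interaction term between each gene's additive eQTL peaks.

    ``R`` must already have covariates, additive effects and polygenic
    background removed; the F statistic tests adding x1*x2 over {x1, x2}
    (which are near-null in R but kept in both nested models).
    """
    n = R.shape[0]
    genes = genes or [f"g{i}" for i in range(R.shape[1])]
    rows = []
    for gi, cols in peaks_per_gene.items():
        if len(cols) < 2:
            continue
        y = R[:, gi]
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                x1 = genotypes.values[:, cols[a]]
                x2 = genotypes.values[:, cols[b]]
                W0 = np.column_stack([np.ones(n), x1, x2])
                W1 = np.column_stack([W0, x1 * x2])
                r0 = y - W0 @ np.linalg.lstsq(W0, y, rcond=None)[0]
                r1 = y - W1 @ np.linalg.lstsq(W1, y, rcond=None)[0]
                rss0, rss1 = float(r0 @ r0), float(r1 @ r1)
                df2 = n - W1.shape[1]
                F = (rss0 - rss1) / max(rss1 / df2, 1e-300)
                ve = interaction_variance(y, x1, x2)
                m1, m2 = sorted((int(cols[a]), int(cols[b])))
                rows.append((genes[gi], m1, m2, float(F), ve))
    return pd.DataFrame(rows, columns=["gene", "marker1", "marker2", "F",
                                       "var_expl"])


def additive_pair_fdr(observed: pd.DataFrame, permuted: list[pd.DataFrame],
                      alpha: float = 0.10,
                      grid: np.ndarray | None = None) -> tuple[float | None, pd.DataFrame]:
    """FDR thresholding of additive-pair F statistics against permutations."""
    if grid is None:
        grid = np.arange(2.0, 60.0, 0.25)
    if observed.empty:
        return None, observed
    for T in grid:
        n_obs = int((observed["F"] > T).sum())
        if n_obs == 0:
            continue
        n_exp = float(np.mean([(p["F"] > T).sum() for p in permuted]))
        if n_exp / n_obs < alpha:
            return float(T), observed[observed["F"] > T].reset_index(drop=True)
    return None, observed.iloc[0:0]


def interaction_variance(y: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> float:
    """Fraction of variance of ``y`` captured by the centered product term
    after removing the marginal fits of ``x1`` and ``x2``."""
    n = len(y)
    W = np.column_stack([np.ones(n), x1, x2])
    ry = y - W @ np.linalg.lstsq(W, y, rcond=None)[0]
    prod = x1 * x2
    rp = prod - W @ np.linalg.lstsq(W, prod, rcond=None)[0]
    denom = float(np.var(y)) * n
    if denom == 0 or rp.std() == 0 or ry.std() == 0:
        return 0.0
    beta = float(rp @ ry / (rp @ rp))
    return float(np.var(beta * rp) / np.var(y))


def marginal_pvalues(y: np.ndarray, x1: np.ndarray, x2: np.ndarray
                     ) -> tuple[float, float]:
    """Two-sided p-values for each marker's marginal (additive) effect on y."""
    out = []
    for x in (x1, x2):
        r = np.corrcoef(x, y)[0, 1]
        n = len(y)
        t = r * np.sqrt((n - 2) / max(1 - r ** 2, 1e-300))
        out.append(2 * sps.t.sf(abs(t), n - 2))
    return out[0], out[1]
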