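"""Multivariate trans-eQTL hotspot (jQTL) fine-mapping.

Genes with trans linkages to a chromosome are residualized against everything
off-chromosome, reduced by SVD to a score matrix ``L``, and scanned with a
determinant-based multivariate LOD: ``(n/2) * log10(|RSS0| / |RSS|)``.
Significant peaks are refined jointly, very strong peaks are tested for a
ghost (two-locus) explanation, and locations get bootstrap confidence
intervals over an 80-marker window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenotypeMatrix, residualize
from .scan import (PermutationConfig, _perm_max_lods, _standardize_over_n,
                   fdr_threshold, lod_scan)

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)


@dataclass
class TransMatrix:
    """Score matrix for one chromosome's shared trans signal."""

    L: np.ndarray                  # n x m component scores
    chromosome: str
    genes: list[str]               # contributing genes
    loadings: np.ndarray | None = None  # genes x m right-singular loadings

    @property
    def m(self) -> int:
        return 0 if self.L is None else self.L.shape[1]


@dataclass
class JqtlPeak:
    index: int                     # marker index within the chromosome
    lod: float
    position: int = 0


@dataclass
class HotspotRecord:
    chromosome: str
    peak_marker: str
    peak_pos: int
    lod: float
    ci_left_pos: int
    ci_right_pos: int
    bootstrap_positions: np.ndarray = field(default_factory=lambda: np.array([]))
    two_locus: bool = False
    subtelomeric: bool = False
    n_targets: int = 0
    target_coefficients: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Residual-factor covariates
# ---------------------------------------------------------------------------

def significant_svd_rank(Rs: np.ndarray, rng: np.random.Generator,
                         k_max: int | None = None, n_perm: int = 10) -> int:
    """Number of singular values exceeding the column-permutation null.

    The null is the largest top singular value over ``n_perm`` independently
    column-permuted copies of the (scaled) residual matrix; one permutation
    leaves the observed and null top values exchangeable under H0, so several
    runs are used to keep the null-rank false-positive rate low.
    """
    s = np.linalg.svd(Rs, compute_uv=False)
    null_max = 0.0
    for _ in range(n_perm):
        Rp = np.empty_like(Rs)
        for j in range(Rs.shape[1]):
            Rp[:, j] = Rs[rng.permutation(Rs.shape[0]), j]
        s_null = np.linalg.svd(Rp, compute_uv=False)
        null_max = max(null_max, float(s_null[0]))
    k = int(np.sum(s > null_max))
    return min(k, k_max) if k_max is not None else k


def _scale_columns(R: np.ndarray) -> np.ndarray:
    Rc = R - R.mean(axis=0)
    sd = Rc.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return Rc / sd


def residual_factor_covariates(expr: ExpressionMatrix, design: np.ndarray,
                               eqtl_markers: dict[str, list[int]],
                               genotypes: GenotypeMatrix,
                               kinship=None, k_max: int = 20,
                               seed: int = 0) -> np.ndarray:
    """Eigenvector covariates for unmodeled shared factors.

    Each gene is residualized on covariates, its significant eQTL markers and
    the whole-genome polygenic BLUP; scaled residuals are decomposed by SVD
    and the top ``min(k_max, k*)`` left-singular columns are returned, where
    ``k*`` counts components beating a column-permutation null.
    """
    from . import mixed
    if not any(eqtl_markers.values()):
        raise ValueError("no genes with detected eQTLs")
    rng = np.random.default_rng(seed)
    n = expr.values.shape[0]
    if kinship is None:
        kinship = mixed.additive_kinship(genotypes)
    lam, U = kinship.eig()
    Dt = U.T @ design
    R = np.empty_like(expr.values)
    for gi, gene in enumerate(expr.genes):
        cols = eqtl_markers.get(gene, [])
        if cols:
            W = np.column_stack([design, genotypes.values[:, cols]])
            Wt = np.column_stack([Dt, U.T @ genotypes.values[:, cols]])
        else:
            W, Wt = design, Dt
        y = expr.values[:, gi]
        delta, beta = mixed._fit_single_rotated(lam, U.T @ y, Wt)
        rf = y - W @ beta
        R[:, gi] = rf - U @ ((lam / (lam + delta)) * (U.T @ rf))
    Rs = _scale_columns(R)
    k = significant_svd_rank(Rs, rng, k_max=k_max)
    if k == 0:
        return np.empty((n, 0))
    Uu, _, _ = np.linalg.svd(Rs, full_matrices=False)
    return Uu[:, :k]


def build_trans_matrix(chromosome: str, expr: ExpressionMatrix,
                       design: np.ndarray,
                       trans_genes: list[str],
                       off_chrom_markers: dict[str, list[int]],
                       genotypes: GenotypeMatrix,
                       seed: int = 0, scale_scores: bool = True) -> TransMatrix:
    """Build the score matrix L for one chromosome.

    ``trans_genes`` must hold genes with a significant trans linkage to the
    chromosome that do not reside on it; each is residualized (OLS, no
    polygenic term) on the covariate design — which should already include the
    unmodeled-factor eigenvectors — plus its off-chromosome eQTL markers.
    Components with singular values beating a column-permutation null are
    kept; scores are left-singular vectors scaled by singular values.
    """
    if not trans_genes:
        return TransMatrix(np.empty((expr.values.shape[0], 0)), chromosome, [])
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(expr.genes)}
    R = np.empty((expr.values.shape[0], len(trans_genes)))
    for k, gene in enumerate(trans_genes):
        cols = off_chrom_markers.get(gene, [])
        W = (np.column_stack([design, genotypes.values[:, cols]])
             if cols else design)
        R[:, k] = residualize(expr.values[:, gene_pos[gene]], W)
    Rs = _scale_columns(R)
    m = significant_svd_rank(Rs, rng)
    m = min(m, min(Rs.shape) - 1) if m else 0
    if m == 0:
        return TransMatrix(np.empty((Rs.shape[0], 0)), chromosome, list(trans_genes))
    Uu, s, Vt = np.linalg.svd(Rs, full_matrices=False)
    L = Uu[:, :m] * s[:m] if scale_scores else Uu[:, :m]
    return TransMatrix(L, chromosome, list(trans_genes), Vt[:m].T)


# ---------------------------------------------------------------------------
# Multivariate LOD
# ---------------------------------------------------------------------------

def mv_lod(L: np.ndarray, x: np.ndarray) -> float:
    """Determinant LOD of one marker against all columns of L."""
    return float(mv_lod_scan(L, np.asarray(x, dtype=float)[:, None])[0])


def mv_lod_scan(L: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Multivariate LOD for every marker column of ``X``.

    Uses the rank-one determinant identity
    |RSS_j| = |RSS0| * (1 - v_j' RSS0^{-1} v_j / x_j'x_j) with
    v_j = Lc' x_cj, so the whole scan costs one m x m solve plus matmuls.
    """
    L = np.asarray(L, dtype=float)
    n, m = L.shape
    if m < 1:
        raise ValueError("L has no columns")
    if n <= m + 2:
        raise ValueError("need n > m + 2 for the multivariate LOD")
    Lc = L - L.mean(axis=0)
    Xc = X - X.mean(axis=0)
    S0 = Lc.T @ Lc
    V = Lc.T @ Xc                            # m x p
    try:
        S0iV = np.linalg.solve(S0, V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular RSS0: collinear columns in L") from exc
    xx = (Xc ** 2).sum(axis=0)
    xx_safe = np.where(xx == 0, 1.0, xx)
    q = np.einsum("mp,mp->p", V, S0iV) / xx_safe
    q = np.where(xx == 0, 0.0, np.clip(q, 0.0, 1.0 - 1e-300))
    return -(n / 2.0) * np.log1p(-q) / LN10


def _pairwise_lod_table(L: np.ndarray, X: np.ndarray) -> np.ndarray:
    """LOD of the two-locus model for every marker pair (dense p x p table)."""
    n, m = L.shape
    Lc = L - L.mean(axis=0)
    Xc = X - X.mean(axis=0)
    S0 = Lc.T @ Lc
    V = Lc.T @ Xc
    S0iV = np.linalg.solve(S0, V)
    Q = V.T @ S0iV                          # p x p: v_i' S0^{-1} v_j
    G = Xc.T @ Xc
    qd = np.diag(Q)
    gd = np.diag(G)
    # det(I2 - W^{-1} M) = det(W - M) / det(W) for each 2x2 pair block
    detW = np.outer(gd, gd) - G ** 2
    diag_term = gd - qd
    offdiag = G - Q
    detWM = np.outer(diag_term, diag_term) - offdiag ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = detWM / detW
    ratio = np.clip(ratio, 1e-300, None)
    lod = -(n / 2.0) * np.log10(ratio)
    np.fill_diagonal(lod, 0.0)
    return lod


def _residualize_on_markers(L: np.ndarray, X: np.ndarray,
                            cols: np.ndarray | list[int]) -> tuple[np.ndarray, np.ndarray]:
    n = L.shape[0]
    if len(cols) == 0:
        return L, X
    W = np.column_stack([np.ones(n), X[:, cols]])
    return residualize(L, W), residualize(X, W)


# ---------------------------------------------------------------------------
# jQTL scan
# ---------------------------------------------------------------------------

def _perm_threshold(L: np.ndarray, X: np.ndarray, n_perm: int, q: float,
                    rng: np.random.Generator) -> float:
    maxes = np.empty(n_perm)
    for k in range(n_perm):
        pi = rng.permutation(L.shape[0])
        maxes[k] = np.max(mv_lod_scan(L[pi], X))
    return float(np.quantile(maxes, q))


def jqtl_scan(trans: TransMatrix, X: np.ndarray, positions: np.ndarray,
              n_perm: int = 100, q: float = 0.99, seed: int = 0,
              max_peaks: int = 20) -> list[JqtlPeak]:
    """Iterative multivariate scan: detect a significant peak, subtract its
    fitted effect from every column of L, repeat until nothing clears the
    permutation threshold (99% quantile of per-permutation max LOD)."""
    if trans.m == 0:
        return []
    rng = np.random.default_rng(seed)
    L = trans.L.copy()
    peaks: list[JqtlPeak] = []
    for _ in range(max_peaks):
        lods = mv_lod_scan(L, X)
        j = int(np.argmax(lods))
        thr = _perm_threshold(L, X, n_perm, q, rng)
        if lods[j] <= thr:
            break
        peaks.append(JqtlPeak(j, float(lods[j]), int(positions[j])))
        xc = X[:, j] - X[:, j].mean()
        b = xc @ (L - L.mean(axis=0)) / (xc @ xc)
        L = L - np.outer(xc, b)
    return peaks


def refine_peaks(trans: TransMatrix, X: np.ndarray, positions: np.ndarray,
                 peaks: list[JqtlPeak], move_limit_bp: int = 75_000
                 ) -> list[JqtlPeak]:
    """Drop-one refinement: rescan each peak's chromosome conditional on all
    other peaks; peaks whose argmax moves more than ``move_limit_bp`` are
    removed, the rest take the refined position."""
    if not peaks:
        return []
    kept: list[JqtlPeak] = []
    current = list(peaks)
    for peak in peaks:
        others = [p.index for p in current if p is not peak]
        Lr, Xr = _residualize_on_markers(trans.L, X, others)
        lods = mv_lod_scan(Lr, Xr)
        j = int(np.argmax(lods))
        if abs(int(positions[j]) - int(positions[peak.index])) > move_limit_bp:
            current = [p for p in current if p is not peak]
            continue
        kept.append(JqtlPeak(j, float(lods[j]), int(positions[j])))
    return kept


def ghost_test(trans: TransMatrix, X: np.ndarray, positions: np.ndarray,
               peak: JqtlPeak, other_peaks: list[JqtlPeak],
               n_perm: int = 100, q: float = 0.99, exclusion: int = 10,
               lod_gate: float = 200.0, margin: float = 10.0, seed: int = 0
               ) -> tuple[bool, list[JqtlPeak]]:
    """Test whether a very strong single peak is a ghost of two flanking loci.

    Only runs for peaks with LOD above ``lod_gate``.  The two-locus model may
    not use markers within ``exclusion`` markers of the original peak.  The
    peak is replaced iff the observed (two-locus - one-locus) LOD gain exceeds
    the permutation 99% quantile of that gain by more than ``margin``.
    """
    if peak.lod <= lod_gate:
        return False, [peak]
    p = X.shape[1]
    excl_lo, excl_hi = peak.index - exclusion, peak.index + exclusion
    allowed = np.array([j for j in range(p) if not excl_lo <= j <= excl_hi])
    if len(allowed) < 2 or allowed.min() > peak.index or allowed.max() < peak.index:
        logger.warning("chromosome too short for the ghost-test exclusion window")
        return False, [peak]
    others = [pk.index for pk in other_peaks]
    Lr, Xr = _residualize_on_markers(trans.L, X, others)

    def delta(Lm: np.ndarray) -> tuple[float, tuple[int, int]]:
        one = float(np.max(mv_lod_scan(Lm, Xr)))
        table = _pairwise_lod_table(Lm, Xr[:, allowed])
        iu = np.triu_indices(len(allowed), k=1)
        best_flat = int(np.argmax(table[iu]))
        two = float(table[iu][best_flat])
        pair = (int(allowed[iu[0][best_flat]]), int(allowed[iu[1][best_flat]]))
        return two - one, pair

    d_obs, pair = delta(Lr)
    rng = np.random.default_rng(seed)
    d_perm = np.empty(n_perm)
    for k in range(n_perm):
        pi = rng.permutation(Lr.shape[0])
        d_perm[k], _ = delta(Lr[pi])
    if d_obs > np.quantile(d_perm, q) + margin:
        lods = mv_lod_scan(Lr, Xr)
        new = [JqtlPeak(j, float(lods[j]), int(positions[j])) for j in pair]
        return True, new
    return False, [peak]


def bootstrap_ci(trans: TransMatrix, X: np.ndarray, positions: np.ndarray,
                 peak: JqtlPeak, other_peaks: list[JqtlPeak],
                 genotypes: GenotypeMatrix | None = None, chrom_markers=None,
                 B: int = 1000, window: int = 80, seed: int = 0
                 ) -> tuple[int, int, np.ndarray]:
    """Central 95% bootstrap CI for a jQTL position.

    Resamples segregants with replacement ``B`` times; per resample the scan
    is restricted to a window of ``window`` markers centered on the observed
    peak, with the other peaks as fixed covariates.  The CI is the [2.5%,
    97.5%] quantile interval of bootstrap peak positions, extended over the
    LD groups of the boundary markers when a genotype map is supplied.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    rng = np.random.default_rng(seed)
    n, p = X.shape
    half = window // 2
    w_lo, w_hi = max(0, peak.index - half), min(p, peak.index + half)
    widx = np.arange(w_lo, w_hi)
    others = [pk.index for pk in other_peaks]
    boot_pos = np.empty(B, dtype=np.int64)
    for b in range(B):
        rows = rng.integers(0, n, size=n)
        Lb, Xb = trans.L[rows], X[rows]
        Lr, Xr = _residualize_on_markers(Lb, Xb, others)
        lods = mv_lod_scan(Lr, Xr[:, widx])
        boot_pos[b] = positions[widx[int(np.argmax(lods))]]
    lo = int(np.quantile(boot_pos, 0.025, method="lower"))
    hi = int(np.quantile(boot_pos, 0.975, method="higher"))
    if genotypes is not None and chrom_markers is not None:
        pos_arr = np.asarray(positions)
        for bound in (lo, hi):
            j = int(np.argmin(np.abs(pos_arr - bound)))
            for member in genotypes.ld_groups.get(chrom_markers[j], []):
                if ":" in member:
                    mp = int(member.rsplit(":", 1)[1])
                    lo, hi = min(lo, mp), max(hi, mp)
    return lo, hi, boot_pos


# ---------------------------------------------------------------------------
# Hotspot target genes
# ---------------------------------------------------------------------------

def hotspot_targets(expr: ExpressionMatrix, design: np.ndarray,
                    genotypes: GenotypeMatrix,
                    hotspot_cols: dict[str, list[int]],
                    off_chrom_markers: dict[str, dict[str, list[int]]],
                    local_marker: dict[str, int] | None = None,
                    cfg: PermutationConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Targeted forward scan at hotspot locations.

    Per chromosome and gene: residualize on covariates plus the gene's
    significant off-chromosome eQTLs, then forward-select from the candidate
    set (the chromosome's hotspot markers plus the gene's closest/local
    marker) under the 5%-FDR permutation criterion; final coefficients come
    from a joint multiple regression.  Returns a tidy frame
    (gene, chrom, marker_col, coefficient).
    """
    cfg = cfg or PermutationConfig(n_permutations=200)
    rng = np.random.default_rng(seed)
    n = expr.values.shape[0]
    rows = []
    for chrom, hcols in hotspot_cols.items():
        if not hcols:
            continue
        # residualize all genes on covariates + off-chromosome eQTLs
        R = np.empty_like(expr.values)
        cand: list[list[int]] = []
        for gi, gene in enumerate(expr.genes):
            off = [j for c, cols in off_chrom_markers.get(gene, {}).items()
                   if c != chrom for j in cols]
            W = (np.column_stack([design, genotypes.values[:, off]])
                 if off else design)
            R[:, gi] = residualize(expr.values[:, gi], W)
            cset = list(hcols)
            if local_marker is not None and gene in local_marker:
                if local_marker[gene] not in cset:
                    cset.append(local_marker[gene])
            cand.append(cset)
        selected = _targeted_forward(R, genotypes.values, cand, cfg, rng)
        for gi, gene in enumerate(expr.genes):
            cols = selected[gi]
            if not cols:
                continue
            W = np.column_stack([np.ones(n), genotypes.values[:, cols]])
            beta = np.linalg.lstsq(W, R[:, gi], rcond=None)[0]
            for c, b in zip(cols, beta[1:]):
                rows.append((gene, chrom, int(c), float(b)))
    return pd.DataFrame(rows, columns=["gene", "chrom", "marker_col", "coefficient"])


def _targeted_forward(R: np.ndarray, G: np.ndarray, candidates: list[list[int]],
                      cfg: PermutationConfig, rng: np.random.Generator
                      ) -> list[list[int]]:
    """Forward selection restricted to per-gene candidate marker sets with a
    shared permutation-grid FDR criterion at each step."""
    n, g = R.shape
    Rw = R.copy()
    active = list(range(g))
    chosen: list[list[int]] = [[] for _ in range(g)]
    while active:
        obs = np.zeros(len(active))
        best = np.zeros(len(active), dtype=int)
        all_cols = sorted({c for ai in active for c in candidates[ai]})
        col_of = {c: k for k, c in enumerate(all_cols)}
        X = G[:, all_cols]
        perms = np.array([rng.permutation(n) for _ in range(cfg.n_permutations)])
        perm_max = np.zeros((cfg.n_permutations, len(active)))
        lod_all, _ = lod_scan(Rw[:, active], X)
        if lod_all.ndim == 1:
            lod_all = lod_all[None, :]
        for k, ai in enumerate(active):
            cols = [col_of[c] for c in candidates[ai] if c not in chosen[ai]]
            if not cols:
                obs[k] = -np.inf
                continue
            remaining = [c for c in candidates[ai] if c not in chosen[ai]]
            sub = lod_all[k, cols]
            obs[k] = sub.max()
            best[k] = remaining[int(np.argmax(sub))]
        Xs = _standardize_over_n(X)
        pm = _perm_max_lods(Rw[:, active], Xs, perms)
        thr = fdr_threshold(np.where(np.isfinite(obs), obs, 0.0), pm, cfg)
        if thr is None:
            break
        sig = obs > thr
        if not sig.any():
            break
        nxt = []
        for k, ai in enumerate(active):
            if sig[k]:
                c = int(best[k])
                chosen[ai].append(c)
                Rw[:, ai] = residualize(
                    Rw[:, ai], np.column_stack([np.ones(n), G[:, c]]))
                if any(cc not in chosen[ai] for cc in candidates[ai]):
                    nxt.append(ai)
        active = nxt
    return chosen


def flag_subtelomeric(records: list[HotspotRecord], genotypes: GenotypeMatrix,
                      margin_bp: int = 5000) -> list[HotspotRecord]:
    """Flag hotspots whose peak lies within ``margin_bp`` of the first or last
    mapped marker on the chromosome."""
    for rec in records:
        cidx = genotypes.chrom_indices(rec.chromosome)
        pos = genotypes.marker_map["pos"].to_numpy()[cidx]
        rec.subtelomeric = (rec.peak_pos - pos.min() < margin_bp
                            or pos.max() - rec.peak_pos < margin_bp)
    return records
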