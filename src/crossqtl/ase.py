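"""Allele-specific expression: balancing, testing, overdispersion, power.

Allele counts per gene (BY vs RM in a hybrid) are balanced by hypergeometric
downsampling, tested against a 1:1 binomial with Bonferroni correction, and
modelled with a beta-binomial whose single overdispersion parameter ``rho``
is estimated at fixed success probability 0.5.  Power is Monte-Carlo over a
grid of (total reads, fold change) or gene-matched to observed coverages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth import simulate_ase_counts


@dataclass
class OverdispersionFit:
    rho: float
    loglik: float
    n_genes: int
    at_boundary: bool = False


# ---------------------------------------------------------------------------
# Downsampling and testing
# ---------------------------------------------------------------------------

def downsample_counts(counts: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Balance BY and RM grand totals by hypergeometric downsampling.

    The allele with the larger grand total is downsampled per gene by a
    multivariate hypergeometric draw (sampling the reduced grand total without
    replacement from the per-gene pools), which preserves each gene's expected
    proportion.  Expects columns ``gene``, ``count_BY``, ``count_RM``.
    """
    rng = np.random.default_rng(seed)
    out = counts.copy()
    tot_by = int(out["count_BY"].sum())
    tot_rm = int(out["count_RM"].sum())
    if tot_by == tot_rm:
        return out
    col = "count_BY" if tot_by > tot_rm else "count_RM"
    target = min(tot_by, tot_rm)
    pools = out[col].to_numpy(dtype=np.int64)
    kept = rng.multivariate_hypergeometric(pools, target)
    out[col] = kept
    return out


def ase_test(counts: pd.DataFrame, min_reads: int = 20,
             n_tests: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Binomial ASE test per gene with Bonferroni correction.

    Genes with fewer than ``min_reads`` total reads are dropped.  The p-value
    is the exact two-sided binomial test of the RM count against p = 0.5;
    significance requires p < alpha / n_tests.  log2 fold change is
    RM/BY, with a 0.5 pseudo-count (and a flag) when either count is zero.
    """
    df = counts.copy()
    df["total"] = df["count_BY"] + df["count_RM"]
    df = df[df["total"] >= min_reads].reset_index(drop=True)
    if n_tests is None:
        n_tests = len(df)
    pvals = np.ones(len(df))
    fc = np.zeros(len(df))
    flagged = np.zeros(len(df), dtype=bool)
    for i, row in df.iterrows():
        k, ntot = int(row["count_RM"]), int(row["total"])
        pvals[i] = stats.binomtest(k, ntot, 0.5).pvalue
        by, rm = float(row["count_BY"]), float(row["count_RM"])
        if by == 0 or rm == 0:
            flagged[i] = True
            by, rm = by + 0.5, rm + 0.5
        fc[i] = np.log2(rm / by)
    df["p_value"] = pvals
    df["log2_fold_change"] = fc
    df["zero_count_flag"] = flagged
    cutoff = alpha / n_tests if n_tests else alpha
    df["bonferroni_significant"] = df["p_value"] < cutoff
    return df


def combine_datasets(tested_a: pd.DataFrame, tested_b: pd.DataFrame,
                     labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Merge two independently tested replicate ASE tables.

    Keeps genes present in either dataset; records whether a gene was
    significant in one or both replicates and averages the log2 fold changes
    where both are available.
    """
    a = tested_a.set_index("gene")
    b = tested_b.set_index("gene")
    genes = sorted(set(a.index) | set(b.index))
    rows = []
    for g in genes:
        in_a, in_b = g in a.index, g in b.index
        sig_a = bool(a.loc[g, "bonferroni_significant"]) if in_a else False
        sig_b = bool(b.loc[g, "bonferroni_significant"]) if in_b else False
        fcs = [df.loc[g, "log2_fold_change"]
               for df, present in ((a, in_a), (b, in_b)) if present]
        rows.append({
            "gene": g,
            "n_datasets": int(in_a) + int(in_b),
            "significant_in": int(sig_a) + int(sig_b),
            "log2_fold_change": float(np.mean(fcs)),
            "datasets": "+".join(lbl for lbl, present
                                 in zip(labels, (in_a, in_b)) if present)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Beta-binomial overdispersion
# ---------------------------------------------------------------------------

def _betabinom_loglik(rho: float, k: np.ndarray, n: np.ndarray,
                      p: float = 0.5) -> float:
    if rho <= 0:
        return float(np.sum(stats.binom.logpmf(k, n, p)))
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return float(np.sum(stats.betabinom.logpmf(k, n, a, b)))


def fit_overdispersion(counts: pd.DataFrame, fixed_p: float = 0.5,
                       min_reads: int = 20) -> OverdispersionFit:
    """MLE of the beta-binomial overdispersion ``rho`` at fixed p.

    Maximizes the summed log-likelihood over genes with total >= ``min_reads``
    by bounded scalar optimization; the rho -> 0 limit is the binomial
    likelihood, and boundary solutions are returned as rho = 0 with a flag.
    """
    tot = (counts["count_BY"] + counts["count_RM"]).to_numpy(dtype=np.int64)
    keep = tot >= min_reads
    if keep.sum() < 10:
        raise ValueError("need at least 10 genes with sufficient reads")
    k = counts["count_RM"].to_numpy(dtype=np.int64)[keep]
    n = tot[keep]
    res = optimize.minimize_scalar(
        lambda r: -_betabinom_loglik(r, k, n, fixed_p),
        bounds=(1e-10, 0.999), method="bounded",
        options={"xatol": 1e-8})
    rho = float(res.x)
    ll0 = _betabinom_loglik(0.0, k, n, fixed_p)
    ll = -float(res.fun)
    if ll0 >= ll:
        return OverdispersionFit(0.0, ll0, int(keep.sum()), at_boundary=True)
    return OverdispersionFit(rho, ll, int(keep.sum()),
                             at_boundary=rho <= 2e-10)


# ---------------------------------------------------------------------------
# Power simulation
# ---------------------------------------------------------------------------

def ase_power(total: int, log2fc: float, rho: float, n_sims: int = 1000,
              alphas: tuple[float, ...] = (0.05, 1.5e-5), seed: int = 0
              ) -> dict:
    """Monte-Carlo power and sign agreement for one (coverage, fold change).

    Simulates beta-binomial counts at p = 2^fc/(1+2^fc), tests each against
    1:1 with the exact binomial test, and reports the detected fraction at
    each alpha plus the fraction with the correct fold-change direction.
    """
    rng = np.random.default_rng(seed)
    counts = simulate_ase_counts(np.full(n_sims, total), log2fc, rho,
                                 n_sims=1, seed=rng)[0]
    pvals = np.array([stats.binomtest(int(k), total, 0.5).pvalue
                      for k in counts])
    power = {f"power_at_{a:g}": float(np.mean(pvals < a)) for a in alphas}
    if log2fc > 0:
        agree = counts > total / 2
    elif log2fc < 0:
        agree = counts < total / 2
    else:
        agree = np.full(n_sims, np.nan)
    power["sign_agreement"] = float(np.nanmean(agree.astype(float))) \
        if log2fc != 0 else float("nan")
    return power


def ase_power_grid(totals: list[int], fold_changes: list[float], rho: float,
                   n_sims: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Power over the full (total, fc) grid; one row per cell."""
    rows = []
    for t in totals:
        for fc in fold_changes:
            res = ase_power(t, fc, rho, n_sims=n_sims,
                            seed=seed + hash((t, round(fc, 6))) % 10_000)
            rows.append({"total": t, "log2fc": fc, **res})
    return pd.DataFrame(rows)


def gene_matched_power(totals: np.ndarray, fold_changes: np.ndarray,
                       rho: float, n_sims: int = 100, alpha: float = 0.05,
                       seed: int = 0) -> pd.DataFrame:
    """Per-gene power at observed coverage and eQTL fold change."""
    rows = []
    for gi, (t, fc) in enumerate(zip(totals, fold_changes)):
        res = ase_power(int(t), float(fc), rho, n_sims=n_sims,
                        alphas=(alpha,), seed=seed + gi)
        rows.append({"gene_index": gi, "total": int(t), "log2fc": float(fc),
                     **res})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standardized major axis regression
# ---------------------------------------------------------------------------

def sma_slope(x: np.ndarray, y: np.ndarray, alpha: float = 0.05
              ) -> dict[str, float]:
    """Standardized major axis fit: slope = sign(r) * sd(y)/sd(x).

    The confidence interval uses the standard SMA formula
    B = F_{1,n-2} * (1 - r^2) / (n - 2); CI = slope * (sqrt(B+1) +/- sqrt(B)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r ** 2) / (n - 2)
    lo = slope * (np.sqrt(B + 1) - np.sqrt(B))
    hi = slope * (np.sqrt(B + 1) + np.sqrt(B))
    if slope < 0:
        lo, hi = hi, lo
    return {"slope": slope, "intercept": intercept, "r2": r ** 2,
            "ci_low": float(lo), "ci_high": float(hi), "n": n}
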