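"""Synthetic two-parent haploid cross generator.

Simulates segregant genotypes as recombinant mosaics of the two parental
haplotypes (Poisson crossover process, no interference — Haldane map), plants
expression phenotypes with additive eQTLs, hotspots, batch/growth nuisance
effects, polygenic background and epistatic pairs, and draws overdispersed
allele-specific read counts.  Every generator is driven by a single explicit
seed and the planted truth is returned as a :class:`TruthTable` ledger so
recovery can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CovariateTable, ExpressionMatrix, GenotypeMatrix


class InvalidDesignError(ValueError):
    """Raised for inconsistent cross designs."""


@dataclass
class Chromosome:
    name: str
    length_bp: int
    genetic_length_morgans: float


@dataclass
class CrossDesign:
    """Layout of a simulated cross: chromosomes, marker positions, panel size."""

    n_segregants: int
    chromosomes: list[Chromosome]
    marker_positions: dict[str, np.ndarray]  # chrom name -> 1-based bp positions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segregants < 2:
            raise InvalidDesignError("need at least 2 segregants")
        for chrom in self.chromosomes:
            if chrom.genetic_length_morgans < 0:
                raise InvalidDesignError(f"negative genetic length on {chrom.name}")
            pos = np.asarray(self.marker_positions[chrom.name])
            if len(pos) and np.any(np.diff(pos) <= 0):
                raise InvalidDesignError(
                    f"marker positions not strictly increasing on {chrom.name}")


def default_design(n_segregants: int = 1012, n_chromosomes: int = 16,
                   markers_per_chrom: int = 125, chrom_length_bp: int = 750_000,
                   genetic_length_morgans: float = 2.8, seed: int = 0) -> CrossDesign:
    """A yeast-like 16-chromosome design with evenly spaced collapsed markers."""
    chroms = []
    positions = {}
    for i in range(n_chromosomes):
        name = f"chr{i + 1:02d}"
        chroms.append(Chromosome(name, chrom_length_bp, genetic_length_morgans))
        positions[name] = np.linspace(
            1, chrom_length_bp, markers_per_chrom).round().astype(np.int64)
    return CrossDesign(n_segregants, chroms, positions, seed)


def simulate_cross(design: CrossDesign, rng: np.random.Generator | None = None
                   ) -> GenotypeMatrix:
    """Simulate segregant genotypes as parental mosaics, coded BY=-1 / RM=+1.

    Crossover counts per chromosome per segregant are Poisson with mean equal
    to the genetic length in Morgans; breakpoints are uniform in bp, so the
    recombinant fraction between markers follows the Haldane map function.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    blocks: list[np.ndarray] = []
    maps: list[pd.DataFrame] = []
    n = design.n_segregants
    for chrom in design.chromosomes:
        pos = np.asarray(design.marker_positions[chrom.name], dtype=np.int64)
        m = len(pos)
        start = rng.choice([-1.0, 1.0], size=n)
        geno = np.empty((n, m))
        n_xo = rng.poisson(chrom.genetic_length_morgans, size=n)
        for i in range(n):
            if n_xo[i] == 0:
                geno[i] = start[i]
                continue
            breaks = np.sort(rng.uniform(0, chrom.length_bp, size=n_xo[i]))
            # parity of crossovers left of each marker flips the parental allele
            flips = np.searchsorted(breaks, pos)
            geno[i] = start[i] * np.where(flips % 2 == 0, 1.0, -1.0)
        blocks.append(geno)
        maps.append(pd.DataFrame({
            "marker": [f"{chrom.name}:{p}" for p in pos],
            "chrom": chrom.name, "pos": pos}))
    marker_map = pd.concat(maps, ignore_index=True)
    return GenotypeMatrix(np.concatenate(blocks, axis=1), marker_map,
                          [f"seg{i:04d}" for i in range(n)])


@dataclass
class TruthTable:
    """Ground-truth ledger for a planted expression simulation."""

    genes: list[str]
    additive: dict[str, list[tuple[str, float]]]  # gene -> [(marker, beta)]
    h2_true: dict[str, float]
    hotspots: list[tuple[str, list[str], dict[str, float]]] = field(default_factory=list)
    # (marker, affected genes, gene -> beta); coefficients also merged into `additive`
    epistatic: list[tuple[str, str, str, float]] = field(default_factory=list)
    # (gene, marker1, marker2, interaction beta)
    batch_coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    growth_coefficients: dict[str, float] = field(default_factory=dict)
    polygenic_var: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, h2 in self.h2_true.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"h2_true for {g} outside [0,1]")

    def to_json(self, path: str) -> None:
        payload = {
            "genes": self.genes,
            "additive": {g: [[m, b] for m, b in v] for g, v in self.additive.items()},
            "h2_true": self.h2_true,
            "hotspots": [[m, gs, coefs] for m, gs, coefs in self.hotspots],
            "epistatic": [list(t) for t in self.epistatic],
            "growth_coefficients": self.growth_coefficients,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def make_truth(genotypes: GenotypeMatrix, n_genes: int, rng: np.random.Generator,
               mean_eqtls_per_gene: float = 3.0, max_eqtls: int = 21,
               median_local_r2: float = 0.02, h2_beta_shape: tuple = (2.6, 7.4),
               n_hotspots: int = 0, hotspot_target_fraction: float = 0.1,
               hotspot_effect_sd: float = 0.3,
               n_epistatic_pairs: int = 0, epistatic_r2: float = 0.022,
               n_batches: int = 13, batch_sd: float = 0.2,
               growth_fraction: float = 0.3, growth_sd: float = 0.2) -> TruthTable:
    """Draw a random planted-truth configuration emulating the study's structure.

    Per-gene eQTL counts are Poisson (capped), effects are small (median r^2
    around ``median_local_r2``), target heritabilities follow a Beta centred
    near 0.26 by default, and hotspots add shared effects to random target sets.
    """
    markers = genotypes.markers
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    additive: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
    h2 = {}
    growth_coefs = {}
    batch_coefs = {}
    for g in genes:
        k = min(int(rng.poisson(mean_eqtls_per_gene)), max_eqtls)
        picks = rng.choice(len(markers), size=k, replace=False) if k else []
        for j in picks:
            # exponential spread of per-eQTL effect sizes around the median r^2
            r2 = median_local_r2 * rng.exponential() / np.log(2)
            beta = np.sqrt(r2) * rng.choice([-1, 1])
            additive[g].append((markers[j], float(beta)))
        h2[g] = float(np.clip(rng.beta(*h2_beta_shape), 0.0, 0.99))
        if rng.random() < growth_fraction:
            growth_coefs[g] = float(rng.normal(0, growth_sd))
        batch_coefs[g] = rng.normal(0, batch_sd, size=n_batches)
    hotspots = []
    if n_hotspots:
        hot_markers = rng.choice(len(markers), size=n_hotspots, replace=False)
        for j in hot_markers:
            n_targets = max(2, int(hotspot_target_fraction * n_genes))
            targets = list(rng.choice(genes, size=n_targets, replace=False))
            coefs = {}
            for g in targets:
                beta = float(rng.normal(0, hotspot_effect_sd))
                additive[g].append((markers[j], beta))
                coefs[g] = beta
            hotspots.append((markers[j], targets, coefs))
    epi = []
    for _ in range(n_epistatic_pairs):
        g = str(rng.choice(genes))
        j1, j2 = rng.choice(len(markers), size=2, replace=False)
        beta = float(np.sqrt(epistatic_r2) * rng.choice([-1, 1]))
        epi.append((g, markers[j1], markers[j2], beta))
    return TruthTable(genes, additive, h2, hotspots, epi, batch_coefs, growth_coefs)


def plant_expression(genotypes: GenotypeMatrix, truth: TruthTable,
                     rng: np.random.Generator | None = None, seed: int = 0,
                     polygenic_fraction: float = 0.3,
                     ) -> tuple[ExpressionMatrix, CovariateTable]:
    """Generate phenotypes from a truth ledger.

    Per gene: planted marker effects + batch shifts + growth effect + a
    polygenic term (small effects at every marker) + Gaussian noise, with the
    noise variance chosen so the realised genetic variance fraction matches
    ``h2_true``.  ``polygenic_fraction`` is the share of genetic variance
    assigned to the diffuse polygenic term for genes that have one.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n, p = genotypes.values.shape
    marker_idx = {m: j for j, m in enumerate(genotypes.markers)}
    genes = truth.genes
    n_batches = max((len(v) for v in truth.batch_coefficients.values()), default=1)
    batch = np.arange(n) % n_batches  # round-robin plate assignment
    growth = rng.normal(0, 1, size=n)
    Y = np.empty((n, len(genes)))
    marker_lookup = genotypes.values
    for gi, g in enumerate(genes):
        h2g = truth.h2_true[g]
        planted = np.zeros(n)
        for m, b in truth.additive.get(g, []):
            planted = planted + b * marker_lookup[:, marker_idx[m]]
        for gene, m1, m2, b in truth.epistatic:
            if gene == g:
                planted = planted + b * (marker_lookup[:, marker_idx[m1]]
                                         * marker_lookup[:, marker_idx[m2]])
        genetic = planted
        has_planted = planted.std() > 0
        if h2g > 0 and (polygenic_fraction > 0 or not has_planted):
            w = rng.normal(0, 1, size=p) / np.sqrt(p)
            poly = marker_lookup @ w
            frac = polygenic_fraction if has_planted else 1.0
            if has_planted:
                poly = poly / poly.std() * planted.std() * np.sqrt(
                    frac / (1 - frac))
            else:
                poly = poly / poly.std()
            genetic = planted + poly
        var_g = genetic.var()
        if h2g <= 0 or var_g == 0:
            noise_sd = 1.0
            genetic = np.zeros(n)
        else:
            noise_sd = np.sqrt(var_g * (1 - h2g) / h2g)
        y = genetic + rng.normal(0, noise_sd, size=n)
        bc = truth.batch_coefficients.get(g)
        if bc is not None:
            y = y + np.asarray(bc)[batch]
        gc = truth.growth_coefficients.get(g)
        if gc:
            y = y + gc * growth
        Y[:, gi] = y
    cov = CovariateTable(np.array([f"b{b:02d}" for b in batch]), growth,
                         list(genotypes.segregants))
    ann = _annotate_genes(genotypes, genes, rng)
    expr = ExpressionMatrix(Y, genes, list(genotypes.segregants), ann)
    return expr, cov


def _annotate_genes(genotypes: GenotypeMatrix, genes: list[str],
                    rng: np.random.Generator) -> pd.DataFrame:
    """Place genes uniformly on the simulated chromosomes (1.5 kb bodies)."""
    chroms = genotypes.chromosomes
    lengths = {c: int(genotypes.marker_map.loc[genotypes.marker_map["chrom"] == c,
                                               "pos"].max()) for c in chroms}
    rows = []
    for g in genes:
        c = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(1, max(2, lengths[c] - 1500)))
        rows.append((g, c, start, start + 1499, "+" if rng.random() < 0.5 else "-"))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])


def simulate_ase_counts(totals: np.ndarray, fold_changes: np.ndarray,
                        rho: float, n_sims: int = 1,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw beta-binomial allele counts (RM-allele successes).

    Success probability per gene is p = 2^fc / (1 + 2^fc) for log2 fold change
    ``fc``; ``rho`` in [0, 1) is the overdispersion (rho = 0 is exactly
    binomial).  Returns an (n_sims, n_genes) array of RM counts.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = np.asarray(totals, dtype=np.int64)
    if (totals < 0).any():
        raise ValueError("totals must be non-negative")
    fc = np.broadcast_to(np.asarray(fold_changes, dtype=float), totals.shape)
    p = 2.0 ** fc / (1.0 + 2.0 ** fc)
    out = np.zeros((n_sims, len(totals)), dtype=np.int64)
    pos = totals > 0
    if rho < 1e-12:  # beta-binomial parameters overflow; exact binomial limit
        out[:, pos] = rng.binomial(totals[pos], p[pos], size=(n_sims, pos.sum()))
    else:
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        out[:, pos] = stats.betabinom.rvs(totals[pos], a[pos], b[pos],
                                          size=(n_sims, pos.sum()), random_state=rng)
    return out
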