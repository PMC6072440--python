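"""Tabular I/O, data filters, and perfect-LD marker collapsing.

Holds the core containers shared across the package: :class:`GenotypeMatrix`
(segregants x markers, coded BY = -1 / RM = +1), :class:`ExpressionMatrix`
(segregants x genes, log2(TPM + 0.5)), and :class:`CovariateTable`.

All on-disk formats are TSV.  Coordinates are 1-based with closed intervals,
following yeast genome convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"  # round-trips float64 exactly


class FilterError(ValueError):
    """Raised when a filtering step leaves an empty matrix."""


@dataclass
class GenotypeMatrix:
    """Segregant genotypes at biallelic markers, coded -1 (BY) / +1 (RM).

    Parameters
    ----------
    values : ndarray of shape (n_segregants, n_markers)
        Genotype codes, entries in {-1, +1}.
    marker_map : DataFrame with columns ``marker``, ``chrom``, ``pos``
        1-based bp positions, sorted by (chrom, pos).
    segregants : list of str
        Row labels.
    ld_groups : dict mapping representative marker -> list of member markers
        Populated by :func:`collapse_perfect_ld`; identity mapping otherwise.
    """

    values: np.ndarray
    marker_map: pd.DataFrame
    segregants: list[str]
    ld_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        if self.values.shape[1] != len(self.marker_map):
            raise ValueError("marker_map length does not match genotype columns")
        if self.values.shape[0] != len(self.segregants):
            raise ValueError("segregant list does not match genotype rows")
        if np.isnan(self.values).any():
            raise ValueError("missing genotypes are not supported; impute upstream")
        bad = ~np.isin(self.values, (-1.0, 1.0))
        if bad.any():
            raise ValueError("genotypes must be coded -1/+1")
        if not self.ld_groups:
            self.ld_groups = {m: [m] for m in self.marker_map["marker"]}

    @property
    def n_segregants(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def markers(self) -> list[str]:
        return list(self.marker_map["marker"])

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.marker_map["chrom"]:
            if c not in seen:
                seen.append(c)
        return seen

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Column indices of markers on ``chrom``."""
        return np.flatnonzero((self.marker_map["chrom"] == chrom).to_numpy())

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        mm = self.marker_map.iloc[idx].reset_index(drop=True)
        groups = {m: self.ld_groups.get(m, [m]) for m in mm["marker"]}
        return GenotypeMatrix(self.values[:, idx], mm, list(self.segregants), groups)

    def positions(self) -> np.ndarray:
        return self.marker_map["pos"].to_numpy(dtype=np.int64)


@dataclass
class ExpressionMatrix:
    """Expression phenotypes (log2(TPM + 0.5)) with gene annotation."""

    values: np.ndarray
    genes: list[str]
    segregants: list[str]
    annotation: pd.DataFrame | None = None
    # annotation columns: gene, chrom, start, end, strand (1-based, closed)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.segregants), len(self.genes)):
            raise ValueError("expression shape does not match labels")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class CovariateTable:
    """Technical covariates: batch factor and a numeric growth measurement."""

    batch: np.ndarray  # categorical codes or labels, one per segregant
    growth: np.ndarray
    segregants: list[str]
    extra: pd.DataFrame | None = None  # appended numeric covariates (eigenvectors)

    def design(self, intercept: bool = True) -> np.ndarray:
        """Dense fixed-effect design: intercept + batch dummies + growth + extras.

        The first batch level is the reference (absorbed by the intercept).
        """
        cols: list[np.ndarray] = []
        n = len(self.segregants)
        if intercept:
            cols.append(np.ones(n))
        levels = pd.unique(pd.Series(self.batch))
        for lv in levels[1:]:
            cols.append((np.asarray(self.batch) == lv).astype(float))
        cols.append(np.asarray(self.growth, dtype=float))
        if self.extra is not None:
            for c in self.extra.columns:
                cols.append(self.extra[c].to_numpy(dtype=float))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_expression(
    tpm: pd.DataFrame,
    read_totals: pd.Series | None = None,
    min_reads: float = 1e6,
    low_value: float = 1.0,
    low_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Apply the study's segregant and transcript filters to a raw TPM matrix.

    Segregants (rows) with fewer than ``min_reads`` total reads are dropped.
    Transcripts (columns) are dropped when identical across all retained
    segregants, or when log2(TPM + 0.5) < ``low_value`` in at least
    ``low_fraction`` of segregants.  Retained values are log2(TPM + 0.5).
    """
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    if read_totals is not None:
        keep = read_totals.reindex(tpm.index) >= min_reads
        tpm = tpm.loc[keep.to_numpy(dtype=bool)]
        if tpm.shape[0] == 0:
            raise FilterError("no segregants pass the read-count filter")
    log_vals = np.log2(tpm.to_numpy(dtype=float) + 0.5)
    constant = np.all(log_vals == log_vals[0:1, :], axis=0)
    low = np.mean(log_vals < low_value, axis=0) >= low_fraction
    keep_genes = ~(constant | low)
    if not keep_genes.any():
        raise FilterError("no transcripts pass the expression filters")
    return ExpressionMatrix(
        values=log_vals[:, keep_genes],
        genes=[g for g, k in zip(tpm.columns, keep_genes) if k],
        segregants=list(tpm.index),
    )


def collapse_perfect_ld(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse markers in perfect LD (identical genotype columns).

    Only *identical* columns are merged — a column and its negation segregate
    through recombination and are kept apart.  The representative is the
    leftmost member by map order; ``ld_groups`` records full membership.
    """
    vals = genotypes.values
    mm = genotypes.marker_map
    rep_idx: list[int] = []
    groups: dict[str, list[str]] = {}
    for chrom in genotypes.chromosomes:
        cidx = genotypes.chrom_indices(chrom)
        seen: dict[bytes, str] = {}
        for j in cidx:
            key = vals[:, j].tobytes()
            name = str(mm["marker"].iloc[j])
            if key in seen:
                groups[seen[key]].append(name)
            else:
                seen[key] = name
                groups[name] = [name]
                rep_idx.append(j)
    idx = np.array(sorted(rep_idx), dtype=int)
    out = genotypes.subset_markers(idx)
    out.ld_groups = {m: groups[m] for m in out.marker_map["marker"]}
    return out


def residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Ordinary-least-squares residuals of ``y`` on the columns of ``design``.

    Rank-deficient designs are handled by the minimum-norm least-squares
    solution (aliased directions contribute nothing to the fit); a warning is
    logged when rank < n_columns.  Supports a 2-D ``y`` (one column per trait).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and response have different lengths")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("design is rank deficient (%d < %d); aliased columns ignored",
                       rank, X.shape[1])
    return y - X @ beta


# ---------------------------------------------------------------------------
# Readers / writers (TSV round-trip safe)
# ---------------------------------------------------------------------------

def write_genotypes(genotypes: GenotypeMatrix, values_path: str, map_path: str) -> None:
    df = pd.DataFrame(genotypes.values.astype(int), index=genotypes.segregants,
                      columns=genotypes.markers)
    df.to_csv(values_path, sep="\t", index_label="segregant")
    mm = genotypes.marker_map.copy()
    mm["ld_members"] = [",".join(genotypes.ld_groups.get(m, [m])) for m in mm["marker"]]
    mm.to_csv(map_path, sep="\t", index=False)


def read_genotypes(values_path: str, map_path: str) -> GenotypeMatrix:
    df = pd.read_csv(values_path, sep="\t", index_col=0, float_precision="round_trip")
    mm = pd.read_csv(map_path, sep="\t", dtype={"marker": str, "chrom": str})
    groups = {}
    if "ld_members" in mm.columns:
        groups = {m: str(v).split(",") for m, v in zip(mm["marker"], mm["ld_members"])}
        mm = mm.drop(columns=["ld_members"])
    if df.isna().to_numpy().any():
        raise ValueError("missing genotypes in input")
    return GenotypeMatrix(df.to_numpy(dtype=float), mm, [str(s) for s in df.index], groups)


def write_expression(expr: ExpressionMatrix, values_path: str,
                     annotation_path: str | None = None) -> None:
    df = pd.DataFrame(expr.values, index=expr.segregants, columns=expr.genes)
    df.to_csv(values_path, sep="\t", index_label="segregant", float_format=FLOAT_FMT)
    if annotation_path is not None and expr.annotation is not None:
        expr.annotation.to_csv(annotation_path, sep="\t", index=False)


def read_expression(values_path: str, annotation_path: str | None = None) -> ExpressionMatrix:
    df = pd.read_csv(values_path, sep="\t", index_col=0, float_precision="round_trip")
    ann = None
    if annotation_path is not None:
        ann = read_annotation(annotation_path)
    return ExpressionMatrix(df.to_numpy(dtype=float), [str(g) for g in df.columns],
                            [str(s) for s in df.index], ann)


def read_annotation(path: str) -> pd.DataFrame:
    """Gene annotation from BED-like TSV (gene, chrom, start, end, strand;
    1-based closed) or GFF3 (only ``gene`` features are parsed)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or (len(first.split("\t")) == 9 and not first.startswith("gene")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9 or parts[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
                gid = attrs.get("ID", attrs.get("Name", parts[8]))
                rows.append((gid, parts[0], int(parts[3]), int(parts[4]), parts[6]))
        return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})


def write_covariates(cov: CovariateTable, path: str) -> None:
    df = pd.DataFrame({"segregant": cov.segregants, "batch": cov.batch,
                       "growth": cov.growth})
    if cov.extra is not None:
        df = pd.concat([df, cov.extra.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_covariates(path: str) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"segregant": str, "batch": str}, float_precision="round_trip")
    extra_cols = [c for c in df.columns if c not in ("segregant", "batch", "growth")]
    extra = df[extra_cols] if extra_cols else None
    return CovariateTable(df["batch"].to_numpy(), df["growth"].to_numpy(dtype=float),
                          list(df["segregant"]), extra)
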