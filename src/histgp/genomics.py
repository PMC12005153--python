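"""Marker QC, imputation, genomic relationships, distances and marker PCA.

The central containers are :class:`MarkerMatrix` (individuals x markers dosage
table, minor-allele coding 0/1/2, ``NaN`` for missing calls) and
:class:`GMatrix` (VanRaden realized-relationship matrix with an id index).
Everything downstream of genotyping — the GBLUP kernels, the training/target
genetic distances, the descriptive PCA — is computed from these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import DataError

__all__ = [
    "MarkerMatrix",
    "GMatrix",
    "QCReport",
    "qc_filter_markers",
    "impute_missing",
    "compute_grm",
    "mean_pairwise_distance",
    "pca_markers",
    "read_hapmap",
    "read_dosage_csv",
]

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


@dataclass
class MarkerMatrix:
    """Individuals x markers dosage matrix.

    Parameters
    ----------
    ids : array of str
        Unique genotype identifiers (row labels).
    dosage : ndarray, shape (n_individuals, n_markers)
        Minor-allele dosages in {0, 1, 2}; ``NaN`` marks missing calls.
    markers : DataFrame
        One row per marker with at least ``chrom`` and ``pos`` columns; the
        index holds marker names. Positions are 1-based (HapMap convention)
        on input/output, any internal arithmetic is positional.
    years : array of labels, optional
        Cohort (birth-year) label per individual; ``None`` entries mark
        genotypes that belong to no single cohort (the repeated checks).
    """

    ids: np.ndarray
    dosage: np.ndarray
    markers: pd.DataFrame
    years: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise DataError("dosage must be a 2-D array")
        if len(self.ids) != self.dosage.shape[0]:
            raise DataError("ids and dosage row count differ")
        if len(self.markers) != self.dosage.shape[1]:
            raise DataError("markers table and dosage column count differ")
        if len(set(self.ids)) != len(self.ids):
            raise DataError("genotype ids must be unique")
        if self.years is not None:
            self.years = np.asarray(self.years, dtype=object)
            if len(self.years) != len(self.ids):
                raise DataError("years and ids length differ")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.dosage) & ((self.dosage < 0) | (self.dosage > 2))
        if bad.any():
            raise DataError("dosage entries must lie in [0, 2] or be missing")

    # -- basic queries ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def row_indexer(self, ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.ids)}
        missing = [g for g in ids if g not in lookup]
        if missing:
            raise DataError(f"ids not in marker matrix: {missing[:5]}")
        return np.array([lookup[g] for g in ids], dtype=int)

    def subset(self, ids=None, marker_mask=None) -> "MarkerMatrix":
        rows = slice(None) if ids is None else self.row_indexer(ids)
        cols = slice(None) if marker_mask is None else marker_mask
        years = None
        if self.years is not None:
            years = self.years[rows]
        return MarkerMatrix(
            ids=self.ids[rows],
            dosage=self.dosage[rows][:, cols],
            markers=self.markers.loc[cols] if marker_mask is not None else self.markers,
            years=years,
        )

    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, from observed calls."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.dosage, index=self.ids, columns=self.markers.index)
        df.index.name = "gid"
        df.to_csv(path)

    def to_hapmap(self, path) -> None:
        """Write as HapMap-style tab text with A/B pseudo-alleles.

        Dosage 0 -> AA, 1 -> AB, 2 -> BB, missing -> NN.
        """
        codes = np.array(["AA", "AB", "BB"])
        rows = []
        for j, (name, mk) in enumerate(self.markers.iterrows()):
            col = self.dosage[:, j]
            geno = np.where(np.isnan(col), "NN", codes[np.nan_to_num(col).astype(int)])
            rows.append(
                [name, "A/B", mk["chrom"], int(mk["pos"]), "+", "NA",
                 "NA", "NA", "NA", "NA", "NA", *geno]
            )
        out = pd.DataFrame(rows, columns=_HAPMAP_META + list(self.ids))
        out.to_csv(path, sep="\t", index=False)


def read_dosage_csv(path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0)
    markers = pd.DataFrame(
        {"chrom": 0, "pos": np.arange(1, df.shape[1] + 1)}, index=df.columns
    )
    return MarkerMatrix(ids=df.index.to_numpy(object), dosage=df.to_numpy(float),
                        markers=markers)


def read_hapmap(path) -> MarkerMatrix:
    """Read HapMap-style tab text written by :meth:`MarkerMatrix.to_hapmap`.

    Genotype cells are two-letter diploid calls; the dosage counts the second
    allele of the ``alleles`` field. ``NN`` (or any call containing N) is
    missing. Positions are kept 1-based as in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta, sample_cols = df.iloc[:, :11], df.columns[11:]
    second = meta["alleles"].str.split("/").str[1].to_numpy()
    calls = df[sample_cols].to_numpy(str)
    dosage = np.full(calls.shape, np.nan)
    for i in range(calls.shape[0]):
        row = calls[i]
        ok = ~np.char.startswith(row.astype(str), "N")
        counts = np.char.count(row.astype(str), second[i])
        dosage[i, ok] = counts[ok]
    markers = pd.DataFrame(
        {"chrom": meta["chrom"].to_numpy(), "pos": meta["pos"].astype(int).to_numpy()},
        index=meta["rs#"].to_numpy(),
    )
    return MarkerMatrix(ids=sample_cols.to_numpy(object), dosage=dosage.T, markers=markers)


@dataclass
class GMatrix:
    """Symmetric realized genomic relationship matrix with an id index."""

    ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataError("G matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("G matrix is not symmetric within 1e-10")
        self._lookup = {g: i for i, g in enumerate(self.ids)}

    def indexer(self, ids) -> np.ndarray:
        missing = [g for g in ids if g not in self._lookup]
        if missing:
            raise DataError(f"ids not in G matrix: {missing[:5]}")
        return np.array([self._lookup[g] for g in ids], dtype=int)

    def submatrix(self, row_ids, col_ids=None) -> np.ndarray:
        ri = self.indexer(row_ids)
        ci = ri if col_ids is None else self.indexer(col_ids)
        return self.values[np.ix_(ri, ci)]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "GMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=df.index.to_numpy(object), values=df.to_numpy(float))


@dataclass
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int
    removed_markers: list = field(default_factory=list)


def qc_filter_markers(m: MarkerMatrix, maf_min: float = 0.05,
                      max_missing: float = 0.5, return_report: bool = False):
    """Remove markers with MAF strictly below ``maf_min`` or missing fraction
    strictly above ``max_missing``; survivor order is preserved.

    A marker at MAF exactly ``maf_min`` is retained (the removal rule is
    "frequency below the threshold").
    """
    maf = m.maf()
    miss = m.missing_rate()
    fail_maf = maf < maf_min
    fail_miss = miss > max_missing
    keep = ~(fail_maf | fail_miss)
    if not keep.any():
        raise DataError("QC removed every marker")
    report = QCReport(
        n_input=m.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_miss.sum()),
        n_retained=int(keep.sum()),
        removed_markers=list(m.markers.index[~keep]),
    )
    out = MarkerMatrix(ids=m.ids, dosage=m.dosage[:, keep],
                       markers=m.markers.loc[keep], years=m.years)
    return (out, report) if return_report else out


def impute_missing(m: MarkerMatrix) -> MarkerMatrix:
    """Replace missing calls by the marker's mean dosage among observed calls.

    Stands where a haplotype-based imputer would run on real sequencing data;
    with the synthetic generator missingness is optional QC plumbing.
    """
    miss = np.isnan(m.dosage)
    if not miss.any():
        return m
    all_missing = miss.all(axis=0)
    if all_missing.any():
        name = m.markers.index[all_missing][0]
        raise DataError(f"marker {name!r} is 100% missing; cannot impute")
    col_mean = np.nanmean(m.dosage, axis=0)
    dosage = np.where(miss, col_mean[None, :], m.dosage)
    return replace(m, dosage=dosage)


def compute_grm(m: MarkerMatrix, freqs: np.ndarray | None = None,
                ridge: float = 0.0) -> GMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    G = W W' / (2 * sum_k p_k (1 - p_k)) with W the dosage matrix centered by
    twice the allele frequency. Frequencies default to the observed
    frequencies of the full supplied matrix (training and target cohorts
    together, mirroring a single relationship matrix built over all years);
    pass ``freqs`` to use an external reference.
    """
    if np.isnan(m.dosage).any():
        raise DataError("G matrix requires complete dosages; impute first")
    p = m.allele_freq() if freqs is None else np.asarray(freqs, float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise DataError("all markers monomorphic: zero VanRaden denominator")
    w = m.dosage - 2.0 * p[None, :]
    g = (w @ w.T) / denom
    g = (g + g.T) / 2.0
    if ridge:
        g = g + ridge * np.eye(len(g))
    return GMatrix(ids=m.ids.copy(), values=g)


def mean_pairwise_distance(m: MarkerMatrix, set_a, set_b,
                           centered: bool = False) -> float:
    """Mean Euclidean distance over all pairs (a in A, b in B) of dosage rows.

    Raw 0/1/2 coding by default; ``centered=True`` subtracts 2p per marker
    first (shifts cancel pairwise, so for complete data both give the same
    value — the option matters only with externally supplied frequencies
    folded in upstream). Overlapping ids are allowed (checks sit in both
    cohorts and contribute their zero self-distances).
    """
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise DataError("distance sets must be non-empty")
    rows_a = m.dosage[m.row_indexer(set_a)]
    rows_b = m.dosage[m.row_indexer(set_b)]
    if np.isnan(rows_a).any() or np.isnan(rows_b).any():
        raise DataError("distance requires complete dosages; impute first")
    if centered:
        shift = 2.0 * m.allele_freq()
        rows_a = rows_a - shift
        rows_b = rows_b - shift
    return float(cdist(rows_a, rows_b, metric="euclidean").mean())


def pca_markers(m: MarkerMatrix, k: int):
    """Principal components of the column-centered dosage matrix.

    Returns ``(scores, variance_explained)`` where scores is (n, k) and
    variance_explained are the fractions of total dosage variance carried by
    each component (non-increasing, summing to <= 1).
    """
    if k <= 0:
        raise DataError("number of components must be positive")
    if k > min(m.n_individuals, m.n_markers):
        raise DataError("k exceeds matrix rank bound")
    if np.isnan(m.dosage).any():
        raise DataError("PCA requires complete dosages; impute first")
    x = m.dosage - m.dosage.mean(axis=0, keepdims=True)
    # deterministic full SVD; matrices here are desk-scale
    u, sing, _ = np.linalg.svd(x, full_matrices=False)
    total = np.sum(sing**2)
    if total == 0:
        raise DataError("zero-variance dosage matrix")
    scores = u[:, :k] * sing[:k]
    var_explained = (sing[:k] ** 2) / total
    return scores, var_explained
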