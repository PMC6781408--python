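"""Genotype containers, VCF I/O, marker filtering, imputation, GRM and PCA.

The central container is :class:`GenotypeMatrix`: an individuals x markers
matrix of alt-allele dosages (0/1/2, ``-1`` for a missing call on integer
matrices, NaN on real-valued matrices after imputation) together with a
per-marker metadata table.  Marker metadata is a plain :class:`pandas.DataFrame`
with at least ``chrom``, ``pos``, ``ref`` and ``alt`` columns; positions are
1-based inclusive, matching VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in integer dosage matrices.
MISSING = -1

_REQUIRED_MARKER_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic markers alt-allele dosage matrix.

    Parameters
    ----------
    dosage
        ``(n_individuals, n_markers)`` array.  Integer matrices use values
        ``{0, 1, 2, MISSING}``; floating matrices (post-imputation) may hold
        fractional dosages and use NaN for missing.
    individual_ids
        Unique identifiers, one per row.
    markers
        Per-marker metadata; one row per column of ``dosage``.  Optional
        columns used downstream: ``cm`` (genetic-map position),
        ``read_count`` (total reads over samples), ``diallelic``,
        ``founder_freq``.
    haplotypes
        Optional ``(n, 2, m)`` phased 0/1 array, carried by the simulator so
        meiosis can recombine parental chromosomes.
    """

    dosage: np.ndarray
    individual_ids: np.ndarray
    markers: pd.DataFrame
    haplotypes: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x markers)")
        n, m = self.dosage.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.markers) != m:
            raise ValueError("markers table length does not match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        for col in _REQUIRED_MARKER_COLUMNS:
            if col not in self.markers.columns:
                raise ValueError(f"markers table missing required column {col!r}")
        if self.haplotypes is not None and self.haplotypes.shape != (n, 2, m):
            raise ValueError("haplotypes must have shape (n, 2, m)")
        self.markers = self.markers.reset_index(drop=True)

    # -- basic queries ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def marker_ids(self) -> pd.Series:
        """``chrom_pos`` identifier per marker."""
        return (
            self.markers["chrom"].astype(str) + "_" + self.markers["pos"].astype(str)
        )

    def missing_mask(self) -> np.ndarray:
        if np.issubdtype(self.dosage.dtype, np.floating):
            return np.isnan(self.dosage)
        return self.dosage == MISSING

    def alt_allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker over non-missing calls (NaN if none)."""
        miss = self.missing_mask()
        d = np.where(miss, 0, self.dosage).astype(float)
        n_called = (~miss).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = d.sum(axis=0) / (2.0 * n_called)
        freq[n_called == 0] = np.nan
        return freq

    def maf(self) -> np.ndarray:
        af = self.alt_allele_freq()
        return np.minimum(af, 1.0 - af)

    # -- subsetting ------------------------------------------------------

    def _individual_indexer(self, individuals) -> np.ndarray:
        individuals = np.asarray(individuals)
        if individuals.dtype == bool:
            return np.flatnonzero(individuals)
        if np.issubdtype(individuals.dtype, np.integer):
            return individuals
        lookup = {iid: i for i, iid in enumerate(self.individual_ids)}
        missing = [x for x in individuals if x not in lookup]
        if missing:
            raise KeyError(f"unknown individual ids: {missing[:5]}")
        return np.array([lookup[x] for x in individuals], dtype=int)

    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        """Row/column subset by ids, integer indices or boolean masks."""
        rows = (
            np.arange(self.n_individuals)
            if individuals is None
            else self._individual_indexer(individuals)
        )
        if markers is None:
            cols = np.arange(self.n_markers)
        else:
            markers = np.asarray(markers)
            cols = np.flatnonzero(markers) if markers.dtype == bool else markers
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(rows, cols)],
            individual_ids=self.individual_ids[rows],
            markers=self.markers.iloc[cols],
            haplotypes=None
            if self.haplotypes is None
            else self.haplotypes[np.ix_(rows, [0, 1], cols)],
        )


def concat_individuals(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices over the same marker set."""
    if len(a.markers) != len(b.markers) or not np.array_equal(
        a.markers["pos"].values, b.markers["pos"].values
    ):
        raise ValueError("marker tables differ; cannot concatenate individuals")
    haps = None
    if a.haplotypes is not None and b.haplotypes is not None:
        haps = np.concatenate([a.haplotypes, b.haplotypes], axis=0)
    return GenotypeMatrix(
        dosage=np.concatenate([a.dosage, b.dosage], axis=0),
        individual_ids=np.concatenate([a.individual_ids, b.individual_ids]),
        markers=a.markers.copy(),
        haplotypes=haps,
    )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT calls) into a :class:`GenotypeMatrix`.

    Diploid GT is mapped to alt-allele dosage; ``./.`` becomes missing.
    Records with more than one ALT allele are kept but flagged
    ``diallelic=False`` for removal by :func:`filter_markers`.  Total read
    count per marker is taken from INFO/DP when present, else from the sum
    of per-sample FORMAT/DP.

    Raises
    ------
    ValueError
        If the file has no sample genotypes or is not coordinate-sorted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if not vcf.samples:
        raise ValueError(f"{path}: VCF has no samples / GT field")
    rows = []
    dosages = []
    for variant in vcf:
        gt = variant.gt_types.astype(np.int8)  # 0/1/2 dosage, 3 = unknown
        gt[gt == 3] = MISSING
        dosages.append(gt)
        read_count = variant.INFO.get("DP")
        if read_count is None:
            try:
                dp = variant.format("DP")
                read_count = int(np.nansum(np.where(dp < 0, 0, dp))) if dp is not None else np.nan
            except Exception:
                read_count = np.nan
        rows.append(
            {
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": ",".join(variant.ALT) if variant.ALT else ".",
                "diallelic": len(variant.ALT) == 1,
                "read_count": read_count,
            }
        )
    samples = np.array(vcf.samples, dtype=object)
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "diallelic", "read_count"])
    _check_sorted(markers, str(path))
    dosage = (
        np.stack(dosages, axis=1) if dosages else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(dosage=dosage, individual_ids=samples, markers=markers)


def _check_sorted(markers: pd.DataFrame, origin: str) -> None:
    seen = []
    for chrom, group in markers.groupby("chrom", sort=False):
        if not np.all(np.diff(group.index) == 1):
            raise ValueError(f"{origin}: chromosome {chrom} records are interleaved; input must be sorted")
        if not group["pos"].is_monotonic_increasing:
            raise ValueError(f"{origin}: positions on chromosome {chrom} are not sorted")
        seen.append(chrom)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write genotypes as plain-text VCF v4.2 (GT; INFO/DP when available)."""
    path = Path(path)
    has_dp = "read_count" in g.markers.columns and g.markers["read_count"].notna().all()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=spgwas\n')
        for chrom in pd.unique(g.markers["chrom"]):
            length = int(g.markers.loc[g.markers["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        if has_dp:
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth over samples">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.individual_ids))
            + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        dosage = g.dosage
        if np.issubdtype(dosage.dtype, np.floating):
            raise ValueError("cannot write real-valued (imputed) dosages as GT calls")
        ids = g.marker_ids().values
        for j in range(g.n_markers):
            row = g.markers.iloc[j]
            info = f"DP={int(row['read_count'])}" if has_dp else "."
            calls = "\t".join(gt_code[int(v)] for v in dosage[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{ids[j]}\t{row['ref']}\t{row['alt']}\t.\tPASS\t{info}\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Filtering and imputation
# ---------------------------------------------------------------------------


def filter_markers(
    g: GenotypeMatrix, min_maf: float = 0.05, min_reads: int = 40
) -> GenotypeMatrix:
    """Keep diallelic markers with MAF >= ``min_maf`` and total reads >= ``min_reads``.

    Boundary handling: exclusion is strict (markers with MAF *below* 0.05 or
    read count *below* 40 are removed), so a marker at exactly the boundary
    survives.  MAF is computed on non-missing calls.  Markers without read
    count information pass the read filter.
    """
    maf = g.maf()
    keep = np.nan_to_num(maf, nan=-1.0) >= min_maf
    if "diallelic" in g.markers.columns:
        keep &= g.markers["diallelic"].to_numpy(dtype=bool)
    if "read_count" in g.markers.columns:
        reads = pd.to_numeric(g.markers["read_count"], errors="coerce").to_numpy(float)
        keep &= ~(reads < min_reads)  # NaN read count passes
    out = g.subset(markers=keep)
    out.markers = out.markers.assign(maf=maf[keep])
    logger.info(
        "filter_markers: %d of %d markers survive (min_maf=%g, min_reads=%d)",
        out.n_markers,
        g.n_markers,
        min_maf,
        min_reads,
    )
    if out.n_markers == 0 and g.n_markers > 0:
        logger.warning("filter_markers removed every marker")
    return out


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker mean dosage (real-valued).

    Non-missing entries are unchanged.  A marker with no non-missing call
    cannot be imputed and raises ``ValueError`` naming the marker.
    """
    miss = g.missing_mask()
    n_called = (~miss).sum(axis=0)
    if np.any(n_called == 0):
        bad = g.marker_ids()[n_called == 0].tolist()
        raise ValueError(f"cannot impute fully-missing markers: {bad[:5]}")
    d = g.dosage.astype(float)
    d[miss] = np.nan
    col_mean = np.nanmean(d, axis=0)
    idx = np.where(miss)
    d[idx] = col_mean[idx[1]]
    return GenotypeMatrix(dosage=d, individual_ids=g.individual_ids, markers=g.markers.copy())


# ---------------------------------------------------------------------------
# GRM and PCA
# ---------------------------------------------------------------------------


def compute_grm(g: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix ``Z Z' / m`` from standardized dosages.

    Each marker is standardized as ``(d - 2p) / sqrt(2 p (1-p))`` with ``p``
    the sample alt-allele frequency; monomorphic (zero-variance) markers are
    dropped before standardization.  Requires an imputed (no-missing) matrix.
    """
    if g.missing_mask().any():
        raise ValueError("compute_grm requires an imputed matrix without missing calls")
    d = g.dosage.astype(float)
    p = d.mean(axis=0) / 2.0
    var = d.var(axis=0)
    use = (p > 0) & (p < 1) & (var > 0)
    m = int(use.sum())
    if m == 0:
        raise ValueError("no polymorphic markers available for the GRM")
    z = (d[:, use] - 2.0 * p[use]) / np.sqrt(2.0 * p[use] * (1.0 - p[use]))
    grm = z @ z.T / m
    return (grm + grm.T) / 2.0


def pca(grm: np.ndarray, k: int):
    """Top-``k`` principal coordinates of a GRM.

    Returns ``(coords, fractions)``: eigenvector coordinates scaled by
    sqrt(eigenvalue), in descending eigenvalue order, and the fraction of
    (non-negative) eigenvalue mass carried by each of the top components.
    """
    grm = np.asarray(grm, dtype=float)
    if grm.ndim != 2 or grm.shape[0] != grm.shape[1]:
        raise ValueError("GRM must be square")
    if not np.allclose(grm, grm.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    if k > grm.shape[0]:
        raise ValueError("k cannot exceed the matrix dimension")
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    coords = vecs[:, :k] * np.sqrt(pos[:k])
    total = pos.sum()
    fractions = pos[:k] / total if total > 0 else np.zeros(k)
    return coords, fractions


def write_grm(grm: np.ndarray, individual_ids: Sequence, path) -> None:
    """Write a GRM as a tab-delimited matrix with id header row and column."""
    pd.DataFrame(grm, index=list(individual_ids), columns=list(individual_ids)).to_csv(
        path, sep="\t", float_format="%.8g"
    )


def read_grm(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), df.index.to_numpy(object)
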