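"""Modified bulk segregant analysis on in-silico bulks.

Bulks are formed computationally from individually genotyped plants (no
DNA pooling).  Per marker, the reference-allele frequency of each bulk is
estimated over non-missing calls; tall and short bulks are contrasted with a
pooled two-proportion Z test; the genome-wide outlier threshold is the
(1 - q) empirical quantile of the raw -log10 p values (q = 0.5% by default);
a centered 15-SNP sliding-window mean smooths the signal within each
chromosome; and significant regions are maximal runs of smoothed values
above the threshold that contain at least one raw outlier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geno import GenotypeMatrix

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


def insilico_bulk_freq(g: GenotypeMatrix, bulk_ids: Sequence) -> pd.DataFrame:
    """Reference-allele frequency of an in-silico bulk, per marker.

    Returns a DataFrame with columns ``chrom, pos, ref_freq, m`` where ``m``
    is the number of called alleles (2 x non-missing bulk members).  Markers
    with no informative call get ``ref_freq = NaN`` and are excluded from
    the scan downstream.
    """
    bulk_ids = np.asarray(bulk_ids, dtype=object)
    if len(bulk_ids) == 0:
        raise ValueError("bulk is empty")
    sub = g.subset(individuals=bulk_ids)
    miss = sub.missing_mask()
    alt = np.where(miss, 0, sub.dosage).astype(float).sum(axis=0)
    m = 2.0 * (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_freq = 1.0 - alt / m
    ref_freq[m == 0] = np.nan
    return pd.DataFrame(
        {
            "chrom": g.markers["chrom"].values,
            "pos": g.markers["pos"].values,
            "ref_freq": ref_freq,
            "m": m.astype(int),
        }
    )


def ztest_scan(tall: pd.DataFrame, short: pd.DataFrame) -> pd.DataFrame:
    """Two-sided pooled two-proportion Z test per marker.

    ``Z = (pT - pS) / sqrt(pbar (1 - pbar) (1/mT + 1/mS))`` with ``pbar`` the
    allele-count-weighted pooled frequency; ``p = 2 Phi(-|Z|)``.  Markers that
    are pooled-monomorphic get ``Z = 0, p = 1``; markers with a missing
    frequency in either bulk are dropped (and counted in the log).
    """
    if len(tall) != len(short) or not np.array_equal(tall["pos"].values, short["pos"].values):
        raise ValueError("bulk frequency tables cover different marker lists")
    pT = tall["ref_freq"].to_numpy(float)
    pS = short["ref_freq"].to_numpy(float)
    mT = tall["m"].to_numpy(float)
    mS = short["m"].to_numpy(float)
    ok = ~(np.isnan(pT) | np.isnan(pS)) & (mT > 0) & (mS > 0)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("ztest_scan: dropping %d markers with missing bulk frequency", n_drop)
    pT, pS, mT, mS = pT[ok], pS[ok], mT[ok], mS[ok]
    pbar = (pT * mT + pS * mS) / (mT + mS)
    var = pbar * (1.0 - pbar) * (1.0 / mT + 1.0 / mS)
    z = np.zeros(len(pbar))
    poly = var > 0
    z[poly] = (pT[poly] - pS[poly]) / np.sqrt(var[poly])
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)
    p[~poly] = 1.0
    return pd.DataFrame(
        {
            "chrom": tall["chrom"].values[ok],
            "pos": tall["pos"].values[ok],
            "ref_freq_tall": pT,
            "ref_freq_short": pS,
            "m_tall": mT.astype(int),
            "m_short": mS.astype(int),
            "zstat": z,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
        }
    )


def outlier_threshold(neglog10p: np.ndarray, q: float = 0.005) -> float:
    """Empirical (1 - q) quantile of genome-wide -log10 p values."""
    x = np.asarray(neglog10p, dtype=float)
    if x.size == 0:
        raise ValueError("no values to compute a threshold from")
    if x.size < 1.0 / q:
        warnings.warn(
            f"only {x.size} values for a {q:.3%} outlier threshold; quantile is unstable",
            stacklevel=2,
        )
    return float(np.quantile(x, 1.0 - q))


def smooth(
    neglog10p: np.ndarray, chrom: np.ndarray, window: int = 15
) -> np.ndarray:
    """Centered ``window``-marker moving average within each chromosome.

    Windows are truncated at chromosome edges and never cross a chromosome
    boundary; markers must be position-sorted within each chromosome.  An
    even window has no center and raises ``ValueError``.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd (centered window)")
    x = pd.Series(np.asarray(neglog10p, dtype=float))
    chrom = pd.Series(np.asarray(chrom, dtype=object))
    out = x.groupby(chrom.values, sort=False).transform(
        lambda s: s.rolling(window, center=True, min_periods=1).mean()
    )
    return out.to_numpy()


@dataclass
class BsaRegion:
    """A contiguous significant genomic interval (1-based, inclusive)."""

    chrom: str
    left: int
    right: int
    length_kb: float
    peak_pos: int
    peak_p: float
    n_markers: int
    n_outliers: int  # markers in the region whose raw value exceeds the threshold


def call_regions(
    smoothed: np.ndarray,
    raw_neglog10p: np.ndarray,
    threshold: float,
    markers: pd.DataFrame,
    gap: int = 15,
) -> list:
    """Call significant regions from smoothed and raw scan values.

    Per chromosome, maximal runs of consecutive markers with smoothed value
    strictly above ``threshold`` are found; runs separated by fewer than
    ``gap`` sub-threshold markers are merged; a region is reported only if it
    contains at least one marker whose *raw* -log10 p exceeds the threshold.
    The peak is the marker with the smallest raw p (ties -> leftmost).
    """
    smoothed = np.asarray(smoothed, dtype=float)
    raw = np.asarray(raw_neglog10p, dtype=float)
    regions: list = []
    for chrom in pd.unique(markers["chrom"]):
        idx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        above = smoothed[idx] > threshold
        runs = _runs(above)
        runs = _merge_runs(runs, gap)
        pos = markers["pos"].to_numpy()[idx]
        for start, stop in runs:  # [start, stop) in chromosome-local indices
            sel = idx[start:stop]
            r = raw[sel]
            n_out = int((r > threshold).sum())
            if n_out == 0:
                continue
            peak_local = int(np.argmax(r))  # leftmost max
            regions.append(
                BsaRegion(
                    chrom=str(chrom),
                    left=int(pos[start]),
                    right=int(pos[stop - 1]),
                    length_kb=(int(pos[stop - 1]) - int(pos[start])) / 1000.0,
                    peak_pos=int(pos[start + peak_local]),
                    peak_p=float(10.0 ** (-r[peak_local])),
                    n_markers=stop - start,
                    n_outliers=n_out,
                )
            )
    return regions


def _runs(mask: np.ndarray) -> list:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_runs(runs: list, gap: int) -> list:
    """Merge runs separated by fewer than ``gap`` markers."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return [tuple(r) for r in merged]


def regions_to_frame(regions: list) -> pd.DataFrame:
    """Region list as a table (Chr, left/right position, length kb, peak SNP, p)."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "left_pos": r.left,
                "right_pos": r.right,
                "length_kb": r.length_kb,
                "peak_pos": r.peak_pos,
                "peak_p": r.peak_p,
                "n_markers": r.n_markers,
                "n_outliers": r.n_outliers,
            }
            for r in regions
        ],
        columns=[
            "chrom", "left_pos", "right_pos", "length_kb",
            "peak_pos", "peak_p", "n_markers", "n_outliers",
        ],
    )


def run_bsa(
    g: GenotypeMatrix,
    tall_ids: Sequence,
    short_ids: Sequence,
    q: float = 0.005,
    window: int = 15,
    gap: int = 15,
):
    """Full BSA pipeline: bulk frequencies -> Z scan -> threshold -> smoothing -> regions.

    The outlier threshold is computed on the raw -log10 p values; run
    detection uses the smoothed values; each region must contain a raw
    outlier.  Returns ``(scan, threshold, regions)`` where ``scan`` carries a
    ``smoothed`` column.
    """
    tall = insilico_bulk_freq(g, tall_ids)
    short = insilico_bulk_freq(g, short_ids)
    scan = ztest_scan(tall, short)
    threshold = outlier_threshold(scan["neg_log10_p"].to_numpy(), q=q)
    scan = scan.assign(
        smoothed=smooth(scan["neg_log10_p"].to_numpy(), scan["chrom"].to_numpy(), window)
    )
    regions = call_regions(
        scan["smoothed"].to_numpy(),
        scan["neg_log10_p"].to_numpy(),
        threshold,
        scan[["chrom", "pos"]],
        gap=gap,
    )
    logger.info(
        "BSA: %d markers scanned, threshold %.3f, %d significant markers, %d regions",
        len(scan), threshold, int((scan["neg_log10_p"] > threshold).sum()), len(regions),
    )
    return scan, threshold, regions
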