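"""Single-plant association scan with pseudo-QTN covariate refinement.

The base scan (:func:`glm_scan`) regresses standardized height residuals on
each marker dosage with fixed covariates (generation and selection-regime
indicators by default).  :func:`pseudo_qtn_scan` wraps it in a simplified
iterative scheme in the spirit of fixed/random-effect multi-locus models:
markers that stand out in the current scan are promoted to covariates
("pseudo-QTNs") after distance pruning and an information-criterion check,
and the scan is repeated until the pseudo-QTN set stabilizes.  The published
multi-locus algorithm it emulates is not replicated bit-exactly; this is a
documented, self-contained stand-in with the same structure (test each
marker in a fixed-effect model conditioned on the current pseudo-QTNs).

Scan results are plain DataFrames with columns ``marker_id, chrom, pos,
effect, se, p_value, neg_log10_p, significant, collinear``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geno import GenotypeMatrix

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class GwasConfig:
    """Association-scan settings.

    ``alpha`` is the genome-wide per-marker significance threshold (markers
    with ``p < alpha`` are called); ``min_qtn_distance`` (bp) keeps the
    pseudo-QTN set spread out; ``candidate_alpha`` is the entry p-value below
    which a marker may be considered for pseudo-QTN status.
    """

    alpha: float = 1e-5
    pseudo_qtn: bool = True
    max_iter: int = 10
    min_qtn_distance: int = 1_000_000
    candidate_alpha: float = 1e-5
    max_pseudo_qtn: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _design(n: int, covariates, extra: Optional[np.ndarray]) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        X = np.column_stack([X, cov])
    if extra is not None and extra.size:
        X = np.column_stack([X, extra])
    return X


def glm_scan(
    g: GenotypeMatrix,
    y: np.ndarray,
    covariates=None,
    extra_covariate_markers: Optional[Sequence[int]] = None,
    chunk_size: int = 20_000,
) -> pd.DataFrame:
    """Per-marker ordinary least squares scan.

    For each marker the model ``y ~ intercept + covariates +
    extra_covariate_markers + dosage`` is fitted and the marker coefficient
    tested with a two-sided t-test.  The covariates are projected out once
    (Frisch-Waugh-Lovell), so the scan is a single pass of matrix products.
    Markers (numerically) collinear with the covariates are flagged and
    assigned ``p = 1``.
    """
    y = np.asarray(y, dtype=float)
    n = g.n_individuals
    if len(y) != n:
        raise ValueError("phenotype length does not match the genotype matrix")
    extra = None
    extra_idx: list = []
    if extra_covariate_markers is not None:
        extra_idx = list(extra_covariate_markers)
        if extra_idx:
            extra = g.dosage[:, extra_idx].astype(float)
    X0 = _design(n, covariates, extra)
    p0 = np.linalg.matrix_rank(X0)
    if n < p0 + 3:
        raise ValueError("too few individuals for the requested model")
    Q, _ = np.linalg.qr(X0)
    ry = y - Q @ (Q.T @ y)
    syy = float(ry @ ry)
    dof = n - X0.shape[1] - 1

    m = g.n_markers
    effect = np.zeros(m)
    se = np.full(m, np.nan)
    pvals = np.ones(m)
    collinear = np.zeros(m, dtype=bool)
    for start in range(0, m, chunk_size):
        stop = min(start + chunk_size, m)
        D = g.dosage[:, start:stop].astype(float)
        RD = D - Q @ (Q.T @ D)
        sxx = np.einsum("ij,ij->j", RD, RD)
        sxy = RD.T @ ry
        bad = sxx <= 1e-8 * n
        sxx_safe = np.where(bad, 1.0, sxx)
        beta = sxy / sxx_safe
        rss = np.maximum(syy - beta * sxy, 0.0)
        sigma2 = rss / dof
        serr = np.sqrt(sigma2 / sxx_safe)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / serr
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        beta[bad] = 0.0
        serr[bad] = np.nan
        p[bad] = 1.0
        effect[start:stop] = beta
        se[start:stop] = serr
        pvals[start:stop] = np.clip(p, _P_FLOOR, 1.0)
        collinear[start:stop] = bad
    res = pd.DataFrame(
        {
            "marker_id": g.marker_ids(),
            "chrom": g.markers["chrom"].values,
            "pos": g.markers["pos"].values,
            "effect": effect,
            "se": se,
            "p_value": pvals,
            "neg_log10_p": -np.log10(pvals),
            "significant": False,
            "collinear": collinear,
        }
    )
    res.attrs["dof"] = dof
    return res


def _prune_by_distance(res: pd.DataFrame, candidates: np.ndarray, min_distance: int) -> list:
    """Greedy p-value-ordered pruning: no two kept markers within ``min_distance``."""
    order = candidates[np.argsort(res["p_value"].to_numpy()[candidates], kind="stable")]
    kept: list = []
    for j in order:
        cj, pj = res["chrom"].iat[j], res["pos"].iat[j]
        if all(res["chrom"].iat[k] != cj or abs(res["pos"].iat[k] - pj) >= min_distance
               for k in kept):
            kept.append(int(j))
    return kept


def _bic(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + X.shape[1] * np.log(n)


def pseudo_qtn_scan(
    g: GenotypeMatrix,
    y: np.ndarray,
    covariates=None,
    cfg: Optional[GwasConfig] = None,
):
    """Iterative scan with pseudo-QTN covariates.

    Each iteration (1) runs :func:`glm_scan` with the current pseudo-QTNs as
    extra covariates (a marker currently in the set is tested by temporarily
    removing itself), (2) forms a candidate set of markers with
    ``p < candidate_alpha``, greedily pruned so no two lie within
    ``min_qtn_distance`` on a chromosome, and (3) retains, in p-value order,
    the candidates whose addition lowers the BIC of the joint fixed-effect
    model.  Iteration stops when the set is unchanged or after ``max_iter``
    rounds (then flagged as non-converged).

    Returns ``(result, pseudo_qtns)``; the result DataFrame carries
    ``attrs['pseudo_qtns']`` and ``attrs['converged']``.
    """
    cfg = cfg or GwasConfig()
    if not cfg.pseudo_qtn:
        res = glm_scan(g, y, covariates)
        res.attrs.update(pseudo_qtns=[], converged=True)
        return res, []
    y = np.asarray(y, dtype=float)
    qtns: list = []
    converged = False
    res = None
    for _ in range(cfg.max_iter):
        res = glm_scan(g, y, covariates, extra_covariate_markers=qtns)
        for j in qtns:  # self-removal: test marker j conditioned on the others
            others = [k for k in qtns if k != j]
            row = glm_scan(g.subset(markers=[j]), y, covariates,
                           extra_covariate_markers=None).iloc[0] \
                if not others else None
            if row is None:
                sub = glm_scan(g, y, covariates, extra_covariate_markers=others)
                row = sub.iloc[j]
            res.iloc[j, res.columns.get_loc("effect")] = row["effect"]
            res.iloc[j, res.columns.get_loc("se")] = row["se"]
            res.iloc[j, res.columns.get_loc("p_value")] = row["p_value"]
            res.iloc[j, res.columns.get_loc("neg_log10_p")] = row["neg_log10_p"]
            res.iloc[j, res.columns.get_loc("collinear")] = row["collinear"]
        pv = res["p_value"].to_numpy()
        candidates = np.flatnonzero(pv < cfg.candidate_alpha)
        pruned = _prune_by_distance(res, candidates, cfg.min_qtn_distance)
        pruned = pruned[: cfg.max_pseudo_qtn]
        new: list = []
        X_base = _design(len(y), covariates, None)
        bic_cur = _bic(y, X_base)
        for j in pruned:
            X_try = np.column_stack([X_base, g.dosage[:, new + [j]].astype(float)])
            bic_try = _bic(y, X_try)
            if bic_try < bic_cur:
                new.append(j)
                bic_cur = bic_try
        if set(new) == set(qtns):
            converged = True
            break
        qtns = new
    if not converged:
        logger.warning("pseudo_qtn_scan did not converge in %d iterations", cfg.max_iter)
    res.attrs.update(pseudo_qtns=list(qtns), converged=converged)
    return res, list(qtns)


def call_significant(res: pd.DataFrame, alpha: float = 1e-5) -> pd.DataFrame:
    """Flag markers with ``p < alpha``; returns the significant subset.

    The input frame's ``significant`` column is updated in place.  The
    expected number of false positives under the global null,
    ``alpha x m``, is logged alongside the observed count.
    """
    sig = res["p_value"].to_numpy() < alpha
    res["significant"] = sig
    logger.info(
        "call_significant: %d markers with p < %g (expected false positives %.2f)",
        int(sig.sum()), alpha, expected_false_positives(alpha, len(res)),
    )
    return res.loc[sig].copy()


def expected_false_positives(alpha: float, n_markers: int) -> float:
    """Expected count of null markers passing a per-marker threshold."""
    return float(alpha) * float(n_markers)


def qq_data(res: pd.DataFrame):
    """Expected vs observed -log10 p quantiles and the genomic inflation factor.

    Observed p-values are sorted ascending and paired with uniform-order
    expectations ``(i - 0.5)/m``.  The inflation factor is
    ``median(chi2(p)) / median(chi2_1)`` (the 0.4549 convention, computed
    exactly from the chi-square quantile function).
    """
    p = np.sort(np.clip(res["p_value"].to_numpy(float), _P_FLOOR, 1.0))
    m = len(p)
    if m == 0:
        raise ValueError("empty scan result")
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(p)
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    df = pd.DataFrame({"expected": expected, "observed": observed})
    return df, lam
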