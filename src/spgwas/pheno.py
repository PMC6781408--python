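"""Phenotype standardization, descriptive statistics, and heritability.

Phenotypes live in a plain :class:`pandas.DataFrame` with columns
``plant_id, plot, year, generation, regime, height_cm`` (see
``simpop.PHENO_COLUMNS``); :func:`standardize` adds a ``residual`` column.

Two heritability estimators are provided:

* :func:`realized_h2` — the breeder's-equation ratio ``h2 = R / S`` where
  ``S`` is the selection differential (mean of the selected parents minus
  the base-population mean) and ``R`` the response (offspring mean minus
  base mean).
* :func:`greml_h2` — single-component GREML: REML variance components for
  ``y = X b + g + e`` with ``g ~ N(0, sigma_g^2 * GRM)``, profiled over the
  variance ratio after one eigendecomposition of the GRM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)


@dataclass
class H2Estimate:
    """A narrow-sense heritability estimate."""

    h2: float
    method: str  # 'greml' or 'breeders'
    sigma_g: Optional[float] = None
    sigma_e: Optional[float] = None
    loglik: Optional[float] = None
    boundary: bool = False  # optimum at (or likelihood flat to) the search boundary
    clamped: bool = False


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"plot": str, "year": str})
    required = {"plant_id", "plot", "year", "generation", "regime", "height_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if (df["height_cm"] <= 0).any():
        raise ValueError("heights must be positive")
    if df["plant_id"].duplicated().any():
        raise ValueError("plant ids must be unique")
    return df


def standardize(phenos: pd.DataFrame) -> pd.DataFrame:
    """Residualize heights on location-year cells (one-factor fixed effect).

    The fitted value of the one-factor model on the plot x year cell is the
    cell mean, so the residual is ``height - cell mean``; residuals sum to
    zero within every cell.  A singleton cell cannot be residualized and is
    assigned residual 0 with a warning.  Returns a copy with a ``residual``
    column; the residuals are the response variable for the association and
    bulk-segregant scans.
    """
    out = phenos.copy()
    cell = out.groupby(["plot", "year"])["height_cm"]
    sizes = cell.transform("size")
    if (sizes < 2).any():
        n_single = int((sizes < 2).sum())
        warnings.warn(
            f"{n_single} plant(s) in singleton location-year cells: residual set to 0",
            stacklevel=2,
        )
    out["residual"] = np.where(
        sizes >= 2, out["height_cm"] - cell.transform("mean"), 0.0
    )
    return out


def describe(phenos: pd.DataFrame, by=("generation", "plot")) -> pd.DataFrame:
    """Per-group descriptive statistics (n, min, max, range, median, mean, sd).

    ``sd`` uses the n-1 denominator and is reported as missing for singleton
    groups.  The default grouping mirrors a per-plot-per-generation field
    trial summary.
    """
    by = [by] if isinstance(by, str) else list(by)
    rows = []
    for key, grp in phenos.groupby(by, sort=True):
        h = grp["height_cm"].to_numpy(float)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(by, key))
            | {
                "n": len(h),
                "min_cm": h.min(),
                "max_cm": h.max(),
                "range_cm": h.max() - h.min(),
                "median_cm": float(np.median(h)),
                "mean_cm": h.mean(),
                "sd_cm": float(np.std(h, ddof=1)) if len(h) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def realized_h2(S: float, R: float) -> H2Estimate:
    """Breeder's-equation realized heritability ``h2 = R / S``.

    ``S`` is the difference between the selected parents' mean and the base
    population mean; ``R`` the difference between the offspring mean and the
    base mean.  The ratio is clamped to [0, 1]; clamping is logged.
    """
    if S == 0:
        raise ValueError("selection differential S must be nonzero")
    h2 = R / S
    clamped = not (0.0 <= h2 <= 1.0)
    if clamped:
        logger.warning("realized_h2: R/S = %.4f clamped into [0, 1]", h2)
        h2 = float(np.clip(h2, 0.0, 1.0))
    return H2Estimate(h2=float(h2), method="breeders", clamped=clamped)


def greml_h2(
    grm: np.ndarray,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    log_lambda_bounds: tuple = (-10.0, 10.0),
    tol: float = 1e-6,
) -> H2Estimate:
    """Single-component GREML heritability.

    Model: ``y = X b + g + e`` with ``g ~ N(0, sigma_g^2 GRM)`` and
    ``e ~ N(0, sigma_e^2 I)``.  The GRM is eigendecomposed once and the
    restricted log-likelihood is profiled in ``lambda = sigma_g^2/sigma_e^2``
    (bounded 1-D search on log lambda); ``h2 = lambda / (1 + lambda)``.
    ``X`` always includes an intercept; extra covariate columns are appended.

    An estimate whose profile likelihood is flat, or whose optimum sits at
    the search boundary, gets ``boundary=True`` (unidentifiable or
    boundary-constrained variance ratio).
    """
    grm = np.asarray(grm, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if grm.shape != (n, n):
        raise ValueError("GRM dimension does not match the phenotype vector")
    if not np.allclose(grm, grm.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    vals, vecs = np.linalg.eigh((grm + grm.T) / 2.0)
    if vals.min() < -1e-6 * max(1.0, vals.max()):
        raise ValueError("GRM is not positive semi-definite beyond tolerance")
    vals = np.clip(vals, 0.0, None)

    X = np.ones((n, 1))
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.column_stack([X, covariates])
    p = X.shape[1]

    ystar = vecs.T @ y
    Xstar = vecs.T @ X

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = lam * vals + 1.0
        Xw = Xstar / w[:, None]
        xtx = Xstar.T @ Xw
        beta = np.linalg.solve(xtx, Xw.T @ ystar)
        r = ystar - Xstar @ beta
        rss = float(r @ (r / w))
        sigma_e2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(sigma_e2)
            + np.log(w).sum()
            + np.linalg.slogdet(xtx)[1]
            + (n - p)
        )
        return -ll

    lo, hi = log_lambda_bounds
    res = minimize_scalar(
        neg_restricted_ll, bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    log_lam = float(res.x)
    ll_opt = -float(res.fun)
    ll_lo, ll_hi = -neg_restricted_ll(lo), -neg_restricted_ll(hi)
    flat = max(abs(ll_opt - ll_lo), abs(ll_opt - ll_hi)) < 1e-6
    boundary = flat or (log_lam - lo < 1e-2) or (hi - log_lam < 1e-2)

    lam = np.exp(log_lam)
    w = lam * vals + 1.0
    Xw = Xstar / w[:, None]
    beta = np.linalg.solve(Xstar.T @ Xw, Xw.T @ ystar)
    r = ystar - Xstar @ beta
    sigma_e2 = float(r @ (r / w)) / (n - p)
    sigma_g2 = lam * sigma_e2
    h2 = sigma_g2 / (sigma_g2 + sigma_e2)
    if boundary:
        logger.info("greml_h2: likelihood optimum at/near the boundary (flat=%s)", flat)
    return H2Estimate(
        h2=float(h2),
        method="greml",
        sigma_g=sigma_g2,
        sigma_e=sigma_e2,
        loglik=ll_opt,
        boundary=boundary,
    )
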