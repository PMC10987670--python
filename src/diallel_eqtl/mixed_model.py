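"""Linear mixed model machinery: kinship, REML heritability, association scan.

The model for a z-scored trait y over n hybrids is

    y = mu * 1 + g + e,   g ~ N(0, sigma2_g * K),   e ~ N(0, sigma2_e * I)

with K the hybrid kinship matrix.  Genome-wide heritability is
h2g = sigma2_g / (sigma2_g + sigma2_e).  Variance components are fit by REML
through a single eigendecomposition K = U diag(lam) U' and bounded 1-D
optimisation of the profiled restricted likelihood over h2.

The association scan fixes the variance components at the null (no-variant)
fit of each trait, rotates trait and genotypes by U', whitens by
(h2*lam + 1 - h2)^(-1/2), and runs per-variant generalised least squares of
the trait on [1, dosage].  The Wald t statistic with n-2 degrees of freedom
gives the p-value; the reported effect size is |beta| per alternate-allele
copy on the z-score scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

_TINY_P = float(np.nextafter(0, 1))
_RIDGE = 1e-8


@dataclass
class KinshipMatrix:
    hybrids: list[str]
    values: np.ndarray
    estimator: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.hybrids)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over the hybrids")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("kinship must be symmetric")


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    h2g: float
    loglik: float
    converged: bool
    degenerate: bool = False


def estimate_kinship(
    matrix: GenotypeMatrix, estimator: str = "centered_grm"
) -> KinshipMatrix:
    """Kinship between hybrids from a (preferably LD-filtered) dosage matrix.

    centered_grm: K = Z Z'/m with Z the column-standardised dosages — the
    default, used throughout the pipeline.  allele_sharing: mean allele
    sharing 1 - |d_i - d_j|/2, rescaled so the minimum off-diagonal is 0
    (popkin-style).  Monomorphic variants are excluded with a warning.
    A ridge of 1e-8 I keeps K numerically PSD.
    """
    x = matrix.dosages.astype(float)
    sd = x.std(axis=0)
    poly = sd > 0
    if (~poly).any():
        logger.warning("kinship: excluding %d monomorphic variants", int((~poly).sum()))
    x = x[:, poly]
    if x.shape[1] == 0:
        raise ValueError("no polymorphic variants for kinship")
    n = x.shape[0]
    if estimator == "centered_grm":
        z = (x - x.mean(axis=0)) / x.std(axis=0)
        k = z @ z.T / x.shape[1]
    elif estimator == "allele_sharing":
        m = x.shape[1]
        # mean over variants of 1 - |d_i - d_j| / 2, computed pairwise
        s = np.empty((n, n))
        for i in range(n):
            s[i] = 1.0 - np.abs(x - x[i]).sum(axis=1) / (2.0 * m)
        off = s[~np.eye(n, dtype=bool)]
        s_min = off.min()
        k = (s - s_min) / (1.0 - s_min)
    else:
        raise ValueError(f"unknown kinship estimator {estimator!r}")
    k = (k + k.T) / 2.0 + _RIDGE * np.eye(n)
    return KinshipMatrix(list(matrix.hybrids), k, estimator)


class EigenKinship:
    """Cached eigendecomposition of K plus the rotated intercept column."""

    def __init__(self, kinship: KinshipMatrix):
        self.hybrids = list(kinship.hybrids)
        lam, u = np.linalg.eigh(kinship.values)
        lam = np.clip(lam, 0.0, None)
        self.lam = lam
        self.u = u
        self.n = len(lam)
        self.x0 = u.T @ np.ones(self.n)
        self.degenerate = (lam.max() - lam.min()) < 1e-10

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.u.T @ a


def _profiled_reml(h2: float, y_rot: np.ndarray, eig: EigenKinship) -> tuple[float, float, float]:
    """Restricted log-likelihood profiled over mu and the total variance.

    Returns (loglik, mu_hat, sigma2_total_hat) at the given h2.
    """
    n = eig.n
    d = h2 * eig.lam + (1.0 - h2)
    w = 1.0 / d
    x0 = eig.x0
    xx = float(np.sum(w * x0 * x0))
    xy = float(np.sum(w * x0 * y_rot))
    mu = xy / xx
    resid = y_rot - mu * x0
    rss = float(np.sum(w * resid * resid))
    sigma2 = rss / (n - 1)
    ll = -0.5 * (
        (n - 1) * np.log(2 * np.pi * sigma2)
        + float(np.sum(np.log(d)))
        + np.log(xx)
        + (n - 1)
    )
    return ll, mu, sigma2


def fit_variance_components(
    y: np.ndarray, kinship: KinshipMatrix | EigenKinship
) -> VarianceComponents:
    """REML fit of (sigma2_g, sigma2_e) for one trait.

    The restricted likelihood is profiled down to h2 and maximised by
    bounded Brent search on [0, 1-1e-6] (tolerance 1e-8).  When K is
    (numerically) the identity, h2 is unidentifiable and the result is
    flagged degenerate.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite trait values")
    eig = kinship if isinstance(kinship, EigenKinship) else EigenKinship(kinship)
    y_rot = eig.rotate(y)

    def neg_ll(h2: float) -> float:
        return -_profiled_reml(h2, y_rot, eig)[0]

    res = optimize.minimize_scalar(
        neg_ll, bounds=(0.0, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    ll, _, sigma2 = _profiled_reml(h2, y_rot, eig)
    # snap to the boundary when it is at least as good (bounded Brent can
    # stall a hair inside the interval)
    for edge in (0.0, 1.0 - 1e-6):
        if _profiled_reml(edge, y_rot, eig)[0] >= ll:
            h2 = edge
            ll, _, sigma2 = _profiled_reml(h2, y_rot, eig)
    converged = bool(res.success) and not (h2 in (0.0, 1.0 - 1e-6))
    return VarianceComponents(
        sigma2_g=h2 * sigma2,
        sigma2_e=(1.0 - h2) * sigma2,
        h2g=h2,
        loglik=ll,
        converged=converged,
        degenerate=eig.degenerate,
    )


def estimate_h2g_panel(
    traits_values: np.ndarray,
    trait_ids: list[str],
    kinship: KinshipMatrix | EigenKinship,
) -> tuple[pd.DataFrame, float]:
    """Per-trait variance components and the panel-wide median h2g.

    ``traits_values`` is genes x hybrids.  Per-trait failures are logged and
    excluded from the median.
    """
    eig = kinship if isinstance(kinship, EigenKinship) else EigenKinship(kinship)
    rows = []
    for tid, y in zip(trait_ids, np.asarray(traits_values, dtype=float)):
        try:
            vc = fit_variance_components(y, eig)
        except ValueError as exc:
            logger.warning("h2 fit failed for trait %s: %s", tid, exc)
            continue
        rows.append(
            {
                "trait_id": tid,
                "h2g": vc.h2g,
                "sigma2_g": vc.sigma2_g,
                "sigma2_e": vc.sigma2_e,
                "loglik": vc.loglik,
                "converged": vc.converged,
            }
        )
    table = pd.DataFrame(rows)
    median = float(table["h2g"].median()) if len(table) else float("nan")
    return table, median


class LMMScanner:
    """Single-variant LMM scan engine with precomputed rotations.

    Rotating the genotype matrix once makes repeated scans (permutation
    thresholds) cheap: each scan is a handful of matrix-vector products.
    """

    def __init__(self, matrix: GenotypeMatrix, kinship: KinshipMatrix | EigenKinship):
        self.eig = kinship if isinstance(kinship, EigenKinship) else EigenKinship(kinship)
        if list(matrix.hybrids) != list(self.eig.hybrids):
            raise ValueError("genotype matrix and kinship hybrids differ")
        self.matrix = matrix
        x = matrix.dosages.astype(float)
        self.poly = x.std(axis=0) > 0
        if (~self.poly).any():
            logger.info("scan: skipping %d zero-variance variants", int((~self.poly).sum()))
        self.g_rot = self.eig.u.T @ x[:, self.poly]
        self.g_rot2 = self.g_rot**2
        self.variant_ids = matrix.variants["id"].to_numpy()[self.poly]
        self.n = self.eig.n

    def fit_null(self, y: np.ndarray) -> VarianceComponents:
        return fit_variance_components(y, self.eig)

    def _gls(self, y: np.ndarray, h2: float):
        """Per-variant GLS of y on [1, dosage] at fixed h2 (vectorised)."""
        eig = self.eig
        d = h2 * eig.lam + (1.0 - h2)
        w = 1.0 / d
        y_rot = eig.rotate(np.asarray(y, dtype=float))
        x0 = eig.x0
        wx0 = w * x0
        wy = w * y_rot
        a11 = float(x0 @ wx0)
        b1 = float(x0 @ wy)
        yy = float(y_rot @ wy)
        a12 = self.g_rot.T @ wx0
        b2 = self.g_rot.T @ wy
        a22 = self.g_rot2.T @ w
        det = a11 * a22 - a12 * a12
        ok = det > 1e-12 * a11 * np.maximum(a22, 1e-300)
        det = np.where(ok, det, np.nan)
        beta0 = (a22 * b1 - a12 * b2) / det
        beta1 = (a11 * b2 - a12 * b1) / det
        rss = np.maximum(yy - beta0 * b1 - beta1 * b2, 0.0)
        df = self.n - 2
        sigma2 = rss / df
        var_beta1 = sigma2 * a11 / det
        se = np.sqrt(var_beta1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta1 / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.clip(p, _TINY_P, 1.0)
        return beta1, se, p, ok

    def scan(self, y: np.ndarray, trait_id: str, h2: float | None = None) -> pd.DataFrame:
        """Full association record stream for one trait."""
        if h2 is None:
            h2 = self.fit_null(y).h2g
        beta, se, p, ok = self._gls(y, h2)
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids[ok],
                "trait_id": trait_id,
                "beta": beta[ok],
                "se": se[ok],
                "p_value": p[ok],
                "effect_size": np.abs(beta[ok]),
                "h2g_null": h2,
            }
        )

    def min_p(self, y: np.ndarray, h2: float | None = None) -> float:
        """Smallest scan p-value for one trait (permutation fast path)."""
        if h2 is None:
            h2 = self.fit_null(y).h2g
        _, _, p, ok = self._gls(y, h2)
        return float(np.nanmin(np.where(ok, p, np.nan)))


def scan_single_variants(
    traits_values: np.ndarray,
    trait_ids: list[str],
    matrix: GenotypeMatrix,
    kinship: KinshipMatrix | EigenKinship,
) -> pd.DataFrame:
    """LMM scan of every variant against every trait.

    Variance components are fit once per trait on the null model and reused
    for all variants of that trait.  Returns the concatenated association
    records (variant_id, trait_id, beta, se, p_value, effect_size).
    """
    scanner = LMMScanner(matrix, kinship)
    frames = [
        scanner.scan(y, tid) for tid, y in zip(trait_ids, np.asarray(traits_values, float))
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["variant_id", "trait_id", "beta", "se", "p_value", "effect_size", "h2g_null"]
    )
    return out
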