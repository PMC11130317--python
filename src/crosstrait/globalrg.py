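"""Global genetic correlation by LD score regression.

Univariate regression of z^2 on N*l/M gives SNP heritability; cross-trait
regression of z1*z2 on sqrt(N1*N2)*l/M gives genetic covariance.  Both use
free intercepts (the cross-trait intercept absorbs sample overlap) and a
two-step heteroscedasticity weighting scheme; standard errors come from a
delete-one block jackknife over contiguous SNP blocks in genome order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from crosstrait.sumstats import PairedSumStats

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


@dataclass
class LdScoreTable:
    """Per-SNP LD scores; ``df`` columns: snp_id, l2 (optionally chrom, pos)."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read(cls, path) -> "LdScoreTable":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        cols = {c.upper(): c for c in df.columns}
        ren = {}
        if "SNP" in cols:
            ren[cols["SNP"]] = "snp_id"
        if "L2" in cols:
            ren[cols["L2"]] = "l2"
        df = df.rename(columns=ren)
        if "snp_id" not in df or "l2" not in df:
            raise ValueError(f"{path}: need SNP and L2 columns")
        return cls(df)

    def write(self, path) -> None:
        out = self.df.rename(columns={"snp_id": "SNP", "l2": "L2"})
        out.to_csv(path, sep="\t", index=False)

    def match(self, snp_ids) -> np.ndarray:
        """LD scores aligned to ``snp_ids``; NaN where unmatched."""
        s = self.df.set_index("snp_id")["l2"]
        return s.reindex(snp_ids).to_numpy(float)


@dataclass
class HeritabilityEstimate:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    M: int
    n_snps: int


@dataclass
class RgEstimate:
    rg: float  # NaN when either h2 <= 0
    se: float
    p: float
    gcov: float
    gcov_se: float
    gcov_p: float
    gcov_intercept: float
    h2_1: float
    h2_2: float
    n_snps: int
    mhc_excluded: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rg)


def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    """Boundaries of ``n_blocks`` contiguous near-equal-size blocks."""
    return np.floor(np.linspace(0, n, n_blocks + 1)).astype(int)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares of y on [x, 1]; returns (slope, intercept)."""
    X = np.column_stack([x, np.ones_like(x)])
    A = (X * w[:, None]).T @ X
    b = (X * w[:, None]).T @ y
    return np.linalg.solve(A, b)


def _wls_jackknife(x, y, w, n_blocks):
    """WLS fit plus delete-one-block coefficient pseudo-estimates.

    Returns (coef, coef_blocks) where coef_blocks has one row per block.
    Uses sufficient statistics so each leave-one-out solve is O(1).
    """
    n = len(x)
    X = np.column_stack([x, np.ones_like(x)])
    XW = X * w[:, None]
    A = XW.T @ X
    b = XW.T @ y
    coef = np.linalg.solve(A, b)

    bounds = _block_bounds(n, n_blocks)
    coef_blocks = np.empty((n_blocks, 2))
    for i in range(n_blocks):
        sl = slice(bounds[i], bounds[i + 1])
        Ai = XW[sl].T @ X[sl]
        bi = XW[sl].T @ y[sl]
        coef_blocks[i] = np.linalg.solve(A - Ai, b - bi)
    return coef, coef_blocks


def _jackknife_se(theta_blocks: np.ndarray) -> float:
    theta_blocks = np.asarray(theta_blocks, float).ravel()
    m = len(theta_blocks)
    mean = theta_blocks.mean()
    return float(np.sqrt((m - 1) / m * ((theta_blocks - mean) ** 2).sum()))


def estimate_h2(
    z: np.ndarray,
    n: np.ndarray | float,
    l: np.ndarray,
    M: int | None = None,
    n_blocks: int = 200,
) -> HeritabilityEstimate:
    """SNP heritability from the regression of z^2 on N*l/M.

    Two-step weights: 1/max(l,1) initially, then divided additionally by
    the squared fitted mean of z^2 (the heteroscedasticity of z^2 under
    normality is 2*E[z^2]^2).  SE by ``n_blocks`` contiguous-block
    jackknife.
    """
    z = np.asarray(z, float)
    l = np.asarray(l, float)
    n = np.broadcast_to(np.asarray(n, float), z.shape)
    ok = np.isfinite(z) & np.isfinite(l)
    z, l, n = z[ok], l[ok], n[ok]
    m_snps = len(z)
    if m_snps < max(200, n_blocks):
        raise ValueError(
            f"estimate_h2: {m_snps} SNPs matched to LD scores; "
            f"need at least {max(200, n_blocks)}"
        )
    if M is None:
        M = m_snps

    x = n * l / M
    y = z**2
    w0 = 1.0 / np.maximum(l, 1.0)
    slope0, int0 = _wls(x, y, w0)
    fitted = np.maximum(int0 + slope0 * x, 0.1)
    w = w0 / (2.0 * fitted**2)

    coef, coef_blocks = _wls_jackknife(x, y, w, n_blocks)
    h2 = float(coef[0])
    se = _jackknife_se(coef_blocks[:, 0:1])
    int_se = _jackknife_se(coef_blocks[:, 1:2])
    return HeritabilityEstimate(
        h2=h2,
        h2_se=max(se, _TINY),
        intercept=float(coef[1]),
        intercept_se=max(int_se, _TINY),
        M=int(M),
        n_snps=m_snps,
    )


def estimate_rg(
    pair: PairedSumStats,
    ld: LdScoreTable,
    M: int | None = None,
    n_blocks: int = 200,
    mhc_excluded: bool = False,
) -> RgEstimate:
    """Bivariate LD score regression with a free cross-trait intercept.

    gcov is the slope of z1*z2 on sqrt(N1*N2)*l/M; rg = gcov/sqrt(h2_1*h2_2).
    The jackknife is taken over the full ratio so the rg SE reflects
    uncertainty in both heritabilities as well as the covariance slope.
    rg is not clipped; |rg| > 1 logs a warning.  When either h2 estimate is
    non-positive rg is NaN but gcov and its significance are still reported.
    """
    l = ld.match(pair.snp_id)
    ok = np.isfinite(l)
    z1, z2 = pair.z1[ok], pair.z2[ok]
    n1, n2 = pair.n1[ok], pair.n2[ok]
    l = l[ok]
    m_snps = len(l)
    if m_snps < max(200, n_blocks):
        raise ValueError(
            f"estimate_rg: only {m_snps} SNPs matched to LD scores"
        )
    if M is None:
        M = m_snps

    lfloor = np.maximum(l, 1.0)
    w0 = 1.0 / lfloor

    # Univariate legs (step-1 then step-2 weights, shared structure).
    def _leg(z, n):
        x = n * l / M
        y = z**2
        s0, i0 = _wls(x, y, w0)
        fitted = np.maximum(i0 + s0 * x, 0.1)
        w = w0 / (2.0 * fitted**2)
        return x, y, w, fitted

    x1, y1, wA, fit1 = _leg(z1, n1)
    x2, y2, wB, fit2 = _leg(z2, n2)

    # Cross leg: Var(z1*z2) ~ fit1*fit2 + fitted-cross^2 under normality.
    xc = np.sqrt(n1 * n2) * l / M
    yc = z1 * z2
    sc0, ic0 = _wls(xc, yc, w0)
    fitc = ic0 + sc0 * xc
    wC = w0 / np.maximum(fit1 * fit2 + fitc**2, 0.1)

    coef1, blocks1 = _wls_jackknife(x1, y1, wA, n_blocks)
    coef2, blocks2 = _wls_jackknife(x2, y2, wB, n_blocks)
    coefc, blocksc = _wls_jackknife(xc, yc, wC, n_blocks)

    h2_1, h2_2 = float(coef1[0]), float(coef2[0])
    gcov = float(coefc[0])
    gcov_se = max(_jackknife_se(blocksc[:, 0:1]), _TINY)
    gcov_p = float(
        min(max(2.0 * stats.norm.sf(abs(gcov) / gcov_se), _TINY), 1.0)
    )

    if h2_1 > 0 and h2_2 > 0:
        rg = gcov / np.sqrt(h2_1 * h2_2)
        prod = blocks1[:, 0] * blocks2[:, 0]
        valid = prod > 0
        if valid.sum() >= 2:
            rg_blocks = blocksc[valid, 0] / np.sqrt(prod[valid])
            se = max(_jackknife_se(rg_blocks), _TINY)
        else:
            se = float("nan")
        p = float(min(max(2.0 * stats.norm.sf(abs(rg) / se), _TINY), 1.0))
        if abs(rg) > 1:
            logger.warning("estimate_rg: |rg| = %.3f exceeds 1 (not clipped)", rg)
    else:
        logger.warning(
            "estimate_rg: non-positive heritability (h2_1=%.4g, h2_2=%.4g); "
            "rg undefined",
            h2_1,
            h2_2,
        )
        rg, se, p = float("nan"), float("nan"), float("nan")

    return RgEstimate(
        rg=float(rg),
        se=float(se),
        p=p,
        gcov=gcov,
        gcov_se=gcov_se,
        gcov_p=gcov_p,
        gcov_intercept=float(coefc[1]),
        h2_1=h2_1,
        h2_2=h2_2,
        n_snps=m_snps,
        mhc_excluded=mhc_excluded,
    )


def significance_label(p: float, n_traits: int = 6) -> str:
    """'significant' below 0.05/n_traits, 'nominal' below 0.05, else 'null'."""
    if p < 0.05 / n_traits:
        return "significant"
    if p < 0.05:
        return "nominal"
    return "null"
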