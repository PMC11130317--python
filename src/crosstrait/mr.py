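"""Two-sample Mendelian randomisation: estimators and sensitivity suite.

Estimators: IVW (multiplicative random effects), MR-Egger with its
intercept-based pleiotropy test, weighted median with bootstrap SE, and
multivariable MR for conditional exposure effects.  Sensitivity: Cochran's
Q heterogeneity, leave-one-out, and an outlier-detection procedure built on
leave-one-out residual sums of squares with a seeded parametric-simulation
null (global, per-SNP outlier, and distortion tests).

Causal effects are log-ORs; results are reported as OR with a 95% CI
(exp(theta -/+ 1.96 se)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from crosstrait.sumstats import PALINDROMIC, SumStatsTable

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny

P_INSTRUMENT = 5e-8
R2_CLUMP = 0.001
CLUMP_WINDOW = 10_000_000
F_MIN = 10.0
EAF_AMBIG_LOW, EAF_AMBIG_HIGH = 0.42, 0.58


class MrError(ValueError):
    pass


@dataclass
class MrEstimate:
    method: str
    theta: float
    se: float
    p: float
    nIV: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.theta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.theta - 1.96 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.theta + 1.96 * self.se))


@dataclass
class PleiotropyTest:
    egger_intercept: float
    se: float
    p: float


@dataclass
class HeterogeneityTest:
    Q: float
    df: int
    p: float


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_indices: list[int]
    outlier_p: np.ndarray
    crude: MrEstimate
    corrected: MrEstimate | None
    distortion_p: float | None


@dataclass
class HarmonizedSet:
    """Instrument-level paired effects aligned to the exposure allele.

    ``df`` columns: snp_id, beta_exp, se_exp, beta_out, se_out,
    eaf_exp, eaf_out.  ``dropped`` audits every instrument removed at
    harmonisation with its reason.
    """

    df: pd.DataFrame
    exposure_label: str = ""
    outcome_label: str = ""
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def f_statistics(self) -> np.ndarray:
        return (self.df["beta_exp"] / self.df["se_exp"]).to_numpy(float) ** 2


def _est(method, theta, se, nIV, p=None, df_t=None) -> MrEstimate:
    se = max(float(se), _TINY)
    if p is None:
        if df_t is not None:
            p = 2.0 * stats.t.sf(abs(theta) / se, df_t)
        else:
            p = 2.0 * stats.norm.sf(abs(theta) / se)
    return MrEstimate(
        method=method,
        theta=float(theta),
        se=se,
        p=float(min(max(p, _TINY), 1.0)),
        nIV=int(nIV),
    )


def select_instruments(
    exposure: SumStatsTable,
    panel,
    p_threshold: float = P_INSTRUMENT,
    r2_threshold: float = R2_CLUMP,
    window: int = CLUMP_WINDOW,
    f_min: float = F_MIN,
) -> list[str]:
    """Greedy LD clumping of genome-wide-significant exposure SNPs.

    Keeps SNPs with p < ``p_threshold`` and F = (beta/se)^2 > ``f_min``,
    then sweeps in ascending p, dropping any remaining SNP within
    ``window`` bp of a kept index SNP at r^2 >= ``r2_threshold`` (panel
    correlations; SNPs in different blocks have r = 0).
    """
    df = exposure.df
    F = (df["beta"] / df["se"]) ** 2
    cand = df[(df["p"] < p_threshold) & (F > f_min)].copy()
    if cand.empty:
        raise MrError("no valid instruments at the significance threshold")
    cand = cand.sort_values("p", kind="mergesort")
    kept: list[pd.Series] = []
    for _, row in cand.iterrows():
        ok = True
        for k in kept:
            if k["chrom"] != row["chrom"]:
                continue
            if abs(int(k["pos"]) - int(row["pos"])) > window:
                continue
            if panel is None or panel.r2_between(k["snp_id"], row["snp_id"]) >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(row)
    return [r["snp_id"] for r in kept]


def harmonize(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    snp_ids: list[str] | None = None,
) -> HarmonizedSet:
    """Align outcome effects to the exposure effect allele.

    Swapped alleles flip the sign of the outcome beta.  Palindromic (A/T,
    C/G) instruments are kept only when both allele frequencies are
    informative and consistent (both < 0.42 or both > 0.58); otherwise
    dropped as strand-ambiguous.  Every removal is recorded in ``dropped``.
    """
    exp_df = exposure.df
    if snp_ids is not None:
        exp_df = exp_df[exp_df["snp_id"].isin(snp_ids)]
    if exp_df.empty:
        raise MrError("harmonize: no instruments supplied")
    m = exp_df.merge(
        outcome.df, on="snp_id", suffixes=("_exp", "_out"), how="left"
    )
    rows, dropped = [], []
    for _, r in m.iterrows():
        sid = r["snp_id"]
        if pd.isna(r.get("beta_out")):
            dropped.append((sid, "absent from outcome"))
            continue
        same = (r["a1_exp"], r["a2_exp"]) == (r["a1_out"], r["a2_out"])
        swapped = (r["a1_exp"], r["a2_exp"]) == (r["a2_out"], r["a1_out"])
        if not (same or swapped):
            dropped.append((sid, "incompatible alleles"))
            continue
        beta_out = float(r["beta_out"]) * (1.0 if same else -1.0)
        eaf_out = r["eaf_out"]
        if swapped and pd.notna(eaf_out):
            eaf_out = 1.0 - float(eaf_out)
        pal = (r["a1_exp"], r["a2_exp"]) in PALINDROMIC
        if pal:
            e1, e2 = r["eaf_exp"], eaf_out
            if pd.isna(e1) or pd.isna(e2):
                dropped.append((sid, "palindromic-ambiguous"))
                continue
            low = e1 < EAF_AMBIG_LOW and e2 < EAF_AMBIG_LOW
            high = e1 > EAF_AMBIG_HIGH and e2 > EAF_AMBIG_HIGH
            if not (low or high):
                dropped.append((sid, "palindromic-ambiguous"))
                continue
        rows.append(
            {
                "snp_id": sid,
                "beta_exp": float(r["beta_exp"]),
                "se_exp": float(r["se_exp"]),
                "beta_out": beta_out,
                "se_out": float(r["se_out"]),
                "eaf_exp": r["eaf_exp"],
                "eaf_out": eaf_out,
            }
        )
    if not rows:
        raise MrError("harmonize: empty harmonized set")
    return HarmonizedSet(
        df=pd.DataFrame(rows),
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        dropped=dropped,
    )


def _xywe(h: HarmonizedSet):
    d = h.df
    return (
        d["beta_exp"].to_numpy(float),
        d["beta_out"].to_numpy(float),
        1.0 / d["se_out"].to_numpy(float) ** 2,
    )


def ivw(h: HarmonizedSet) -> MrEstimate:
    """Inverse-variance-weighted estimate (multiplicative random effects).

    Weighted regression of beta_out on beta_exp through the origin with
    weights 1/se_out^2; the SE is inflated by max(1, sqrt(Q/df)) and never
    deflated below the fixed-effects value.
    """
    n = len(h)
    if n < 2:
        raise MrError("IVW needs at least 2 instruments")
    bx, by, w = _xywe(h)
    sxx = float(np.sum(w * bx * bx))
    theta = float(np.sum(w * bx * by)) / sxx
    se_fixed = 1.0 / np.sqrt(sxx)
    Q = float(np.sum(w * (by - theta * bx) ** 2))
    scale = max(1.0, np.sqrt(Q / (n - 1)))
    return _est("IVW", theta, se_fixed * scale, n)


def mr_egger(h: HarmonizedSet) -> tuple[MrEstimate, PleiotropyTest]:
    """Egger regression: free intercept absorbs directional pleiotropy.

    Slope and intercept tested with t (nIV - 2 df); residual scale floored
    at 1 (random effects never deflate the SE).
    """
    n = len(h)
    if n < 3:
        raise MrError("MR-Egger needs at least 3 instruments")
    bx, by, w = _xywe(h)
    # orient to positive exposure effects (standard Egger convention)
    sgn = np.sign(bx)
    sgn[sgn == 0] = 1.0
    bx, by = bx * sgn, by * sgn
    X = np.column_stack([bx, np.ones(n)])
    A = (X * w[:, None]).T @ X
    b = (X * w[:, None]).T @ by
    coef = np.linalg.solve(A, b)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (n - 2)
    cov = max(sigma2, 1.0) * np.linalg.inv(A)
    slope_se = float(np.sqrt(cov[0, 0]))
    int_se = float(np.sqrt(cov[1, 1]))
    est = _est("Egger", coef[0], slope_se, n, df_t=n - 2)
    p_int = float(
        min(max(2.0 * stats.t.sf(abs(coef[1]) / max(int_se, _TINY), n - 2), _TINY), 1.0)
    )
    return est, PleiotropyTest(
        egger_intercept=float(coef[1]), se=int_se, p=p_int
    )


def _ratio_stats(h: HarmonizedSet):
    d = h.df[h.df["beta_exp"] != 0]
    if len(d) < len(h.df):
        logger.warning(
            "weighted_median: %d instrument(s) with beta_exp = 0 excluded",
            len(h.df) - len(d),
        )
    bx = d["beta_exp"].to_numpy(float)
    by = d["beta_out"].to_numpy(float)
    se_x = d["se_exp"].to_numpy(float)
    se_y = d["se_out"].to_numpy(float)
    ratio = by / bx
    se_ratio = np.sqrt(se_y**2 / bx**2 + by**2 * se_x**2 / bx**4)
    return bx, by, se_x, se_y, ratio, se_ratio


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted median of per-instrument ratio estimates.

    Weights are inverse squared delta-method ratio SEs; the SE comes from a
    seeded parametric bootstrap (default 1,000 replicates).
    """
    if len(h) < 3:
        raise MrError("weighted median needs at least 3 instruments")
    bx, by, se_x, se_y, ratio, se_ratio = _ratio_stats(h)
    w = 1.0 / se_ratio**2
    theta = _weighted_median(ratio, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx + rng.standard_normal(len(bx)) * se_x
        bys = by + rng.standard_normal(len(by)) * se_y
        ok = bxs != 0
        r = bys[ok] / bxs[ok]
        sr = np.sqrt(
            se_y[ok] ** 2 / bxs[ok] ** 2 + bys[ok] ** 2 * se_x[ok] ** 2 / bxs[ok] ** 4
        )
        boots[i] = _weighted_median(r, 1.0 / sr**2)
    return _est("WeightedMedian", theta, np.std(boots, ddof=1), len(bx))


def cochran_q(h: HarmonizedSet, theta: float) -> HeterogeneityTest:
    """Q = sum w_i (ratio_i - theta)^2 against chi-square(nIV - 1)."""
    if len(h) < 2:
        raise MrError("Cochran's Q needs at least 2 instruments")
    *_, ratio, se_ratio = _ratio_stats(h)
    w = 1.0 / se_ratio**2
    Q = float(np.sum(w * (ratio - theta) ** 2))
    df = len(ratio) - 1
    return HeterogeneityTest(Q=Q, df=df, p=float(stats.chi2.sf(Q, df)))


def leave_one_out(h: HarmonizedSet) -> list[tuple[str, MrEstimate]]:
    """IVW re-estimated with each instrument omitted in turn."""
    n = len(h)
    if n < 3:
        raise MrError("leave-one-out needs at least 3 instruments")
    out = []
    for i in range(n):
        sub = HarmonizedSet(
            df=h.df.drop(h.df.index[i]).reset_index(drop=True),
            exposure_label=h.exposure_label,
            outcome_label=h.outcome_label,
        )
        out.append((h.df["snp_id"].iloc[i], ivw(sub)))
    return out


def _loo_theta(bx, by, w):
    """Leave-one-out IVW slopes for every instrument, vectorised."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    significance: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier procedure.

    Global test: observed weighted leave-one-out residual sum of squares
    against a seeded parametric-simulation null (outcome betas redrawn
    about their leave-one-out fitted values).  Outlier test: per-SNP
    residual against its simulated distribution, Bonferroni over nIV.
    Corrected estimate: IVW on non-outliers, emitted only when outliers are
    found; the distortion test compares crude vs corrected via seeded
    resampling of pseudo-outlier subsets.
    """
    n = len(h)
    if n < 4:
        raise MrError("insufficient instruments for PRESSO (need >= 4)")
    bx, by, w = _xywe(h)
    se_out = h.df["se_out"].to_numpy(float)
    rng = np.random.default_rng(seed)

    theta_loo = _loo_theta(bx, by, w)
    obs_res2 = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_res2))

    # simulated outcome betas about the leave-one-out fitted values
    by_sim = theta_loo[None, :] * bx[None, :] + rng.standard_normal(
        (n_sim, n)
    ) * se_out[None, :]
    sxy_sim = by_sim @ (w * bx)
    sxx = float(np.sum(w * bx * bx))
    theta_loo_sim = (sxy_sim[:, None] - (w * bx * by_sim)) / (
        sxx - (w * bx * bx)[None, :]
    )
    res2_sim = w[None, :] * (by_sim - theta_loo_sim * bx[None, :]) ** 2
    rss_sim = res2_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outlier_p = (1 + (res2_sim >= obs_res2[None, :]).sum(axis=0)) / (n_sim + 1)
    flagged = [int(i) for i in np.where(outlier_p < significance / n)[0]]

    crude = ivw(h)
    corrected = None
    distortion_p = None
    if flagged:
        keep = np.setdiff1d(np.arange(n), flagged)
        if len(keep) < 2:
            raise MrError("PRESSO: too few non-outlier instruments remain")
        sub = HarmonizedSet(
            df=h.df.iloc[keep].reset_index(drop=True),
            exposure_label=h.exposure_label,
            outcome_label=h.outcome_label,
        )
        corrected = ivw(sub)
        corrected = MrEstimate(
            method="PRESSO-corrected",
            theta=corrected.theta,
            se=corrected.se,
            p=corrected.p,
            nIV=corrected.nIV,
        )
        d_obs = (crude.theta - corrected.theta) / max(abs(corrected.theta), _TINY)
        d_null = np.empty(n_sim)
        for b in range(n_sim):
            pseudo = rng.choice(keep, size=len(flagged), replace=True)
            mask = np.setdiff1d(np.arange(n), pseudo)
            sxx_b = np.sum(w[mask] * bx[mask] ** 2)
            th_b = np.sum(w[mask] * bx[mask] * by[mask]) / sxx_b
            d_null[b] = (crude.theta - th_b) / max(abs(th_b), _TINY)
        distortion_p = float(
            (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1)
        )
    crude = MrEstimate(
        method="PRESSO-crude",
        theta=crude.theta,
        se=crude.se,
        p=crude.p,
        nIV=crude.nIV,
    )
    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_indices=flagged,
        outlier_p=outlier_p,
        crude=crude,
        corrected=corrected,
        distortion_p=distortion_p,
    )


def mvmr(
    exposures: list[SumStatsTable],
    outcome: SumStatsTable,
    panel,
    p_threshold: float = P_INSTRUMENT,
    r2_threshold: float = R2_CLUMP,
    window: int = CLUMP_WINDOW,
) -> list[MrEstimate]:
    """Multivariable MR: conditional effect of each exposure on the outcome.

    Candidates are retrieved per exposure, pooled, jointly clumped (rank by
    the smallest p across exposures), re-extracted from every exposure and
    the outcome, and fitted by weighted multiple regression through the
    origin with weights 1/se_out^2.  SEs use a multiplicative scale
    max(1, sqrt(Q/df)).
    """
    if len(exposures) < 2:
        raise MrError("MVMR needs at least 2 exposures")
    cand: set[str] = set()
    for ex in exposures:
        try:
            cand.update(select_instruments(ex, panel, p_threshold, r2_threshold, window))
        except MrError:
            continue
    if not cand:
        raise MrError("MVMR: no candidate instruments in any exposure")

    # joint clump on the pooled candidates, ranked by best p across exposures
    frames = []
    for ex in exposures:
        sub = ex.df[ex.df["snp_id"].isin(cand)][["snp_id", "chrom", "pos", "p"]]
        frames.append(sub)
    pooled = (
        pd.concat(frames)
        .sort_values("p", kind="mergesort")
        .drop_duplicates("snp_id")
    )
    kept: list[pd.Series] = []
    for _, row in pooled.iterrows():
        ok = True
        for k in kept:
            if k["chrom"] != row["chrom"]:
                continue
            if abs(int(k["pos"]) - int(row["pos"])) > window:
                continue
            if panel is None or panel.r2_between(k["snp_id"], row["snp_id"]) >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(row)
    snps = [r["snp_id"] for r in kept]

    # re-extract from every exposure and the outcome; require completeness
    first = exposures[0].df.set_index("snp_id")
    avail = set(snps)
    for ex in exposures:
        avail &= set(ex.df["snp_id"])
    avail &= set(outcome.df["snp_id"])
    snps = [s for s in snps if s in avail]
    k = len(exposures)
    if len(snps) <= k:
        raise MrError(
            f"MVMR: {len(snps)} instruments after clumping for {k} exposures"
        )

    def _aligned_beta(tab: SumStatsTable, snps: list[str]) -> np.ndarray:
        d = tab.df.set_index("snp_id").loc[snps]
        sign = np.where(
            (d["a1"].to_numpy() == first.loc[snps, "a1"].to_numpy())
            & (d["a2"].to_numpy() == first.loc[snps, "a2"].to_numpy()),
            1.0,
            -1.0,
        )
        return sign * d["beta"].to_numpy(float)

    X = np.column_stack([_aligned_beta(ex, snps) for ex in exposures])
    y = _aligned_beta(outcome, snps)
    se_out = outcome.df.set_index("snp_id").loc[snps, "se"].to_numpy(float)
    w = 1.0 / se_out**2
    A = (X * w[:, None]).T @ X
    if np.linalg.cond(A) > 1e10:
        raise MrError("MVMR: rank-deficient (collinear exposures)")
    coef = np.linalg.solve(A, (X * w[:, None]).T @ y)
    resid = y - X @ coef
    Q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(Q / (len(snps) - k)))
    cov = np.linalg.inv(A) * scale**2
    out = []
    for j, ex in enumerate(exposures):
        out.append(
            _est(
                f"MVMR[{ex.trait_label or j}]",
                coef[j],
                float(np.sqrt(cov[j, j])),
                len(snps),
            )
        )
    return out


def run_direction(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    panel,
    seed: int = 0,
    p_threshold: float = P_INSTRUMENT,
    exclusions: set[str] | None = None,
) -> dict:
    """Full estimator + sensitivity suite for one direction."""
    snps = select_instruments(exposure, panel, p_threshold=p_threshold)
    if exclusions:
        snps = [s for s in snps if s not in exclusions]
        if not snps:
            raise MrError("all instruments excluded")
    h = harmonize(exposure, outcome, snps)
    res: dict = {"harmonized": h, "n_instruments": len(h)}
    res["ivw"] = ivw(h)
    res["heterogeneity"] = cochran_q(h, res["ivw"].theta)
    if len(h) >= 3:
        res["egger"], res["pleiotropy"] = mr_egger(h)
        res["weighted_median"] = weighted_median(h, seed=seed)
        res["leave_one_out"] = leave_one_out(h)
    if len(h) >= 4:
        res["presso"] = mr_presso(h, seed=seed)
    return res


def run_bidirectional(
    traitA: SumStatsTable,
    traitB: SumStatsTable,
    panel,
    n_traits_tested: int = 6,
    seed: int = 0,
    p_threshold: float = P_INSTRUMENT,
    exclusions: set[str] | None = None,
) -> dict:
    """Both causal directions with significance labels.

    'significant' below 0.05/n_traits_tested, 'nominal' below 0.05.  A
    failed direction is reported under an 'error' key; the other direction
    still runs.
    """
    threshold = 0.05 / n_traits_tested
    report: dict = {"threshold": threshold}
    for key, (exp, out) in {
        "forward": (traitA, traitB),
        "reverse": (traitB, traitA),
    }.items():
        try:
            r = run_direction(
                exp, out, panel, seed=seed, p_threshold=p_threshold,
                exclusions=exclusions,
            )
            p = r["ivw"].p
            r["label"] = (
                "significant" if p < threshold else "nominal" if p < 0.05 else "null"
            )
            report[key] = r
        except MrError as exc:
            report[key] = {"error": str(exc)}
    return report
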