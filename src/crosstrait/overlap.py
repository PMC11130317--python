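"""Gene-level overlap statistics across two traits.

Counts genes below a nominal threshold in a discovery and a target set over
their shared gene universe, tests whether the observed overlap proportion
exceeds the expected proportion with a one-sided exact binomial test,
combines per-gene P values with Fisher's method (chi-square, 4 df), and
classifies shared genes into three categories plus a sentinel-shared label.

Gene tables are tab-delimited with columns GENE CHR START STOP NSNPS P.
All thresholds are strict ("<").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

_TINY = np.finfo(float).tiny

GENE_COLUMNS = ["GENE", "CHR", "START", "STOP", "NSNPS", "P"]


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    missing = [c for c in ("GENE", "P") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df["GENE"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    if not ((df["P"] > 0) & (df["P"] <= 1)).all():
        raise ValueError(f"{path}: gene P values must lie in (0, 1]")
    return df


@dataclass
class OverlapCounts:
    total_genes: int
    x: int  # discovery-set genes below alpha
    y: int  # target-set genes below alpha
    z: int  # genes below alpha in both


@dataclass
class OverlapTestResult:
    e: float  # expected proportion = x / total_genes
    o_obs: float  # observed proportion = z / y
    p_binomial: float


@dataclass
class FcpResult:
    gene_id: str
    p1: float
    p2: float
    p_fcp: float
    category: str  # "1" | "2" | "3" | "1∩2" | "none"


def _universe(t1: pd.DataFrame, t2: pd.DataFrame) -> pd.DataFrame:
    m = t1[["GENE", "P"]].merge(
        t2[["GENE", "P"]], on="GENE", suffixes=("_1", "_2")
    )
    if m.empty:
        raise ValueError("empty shared gene universe")
    return m


def count_overlap(
    discovery: pd.DataFrame, target: pd.DataFrame, alpha: float = 0.05
) -> OverlapCounts:
    """Hit counts over the shared gene universe at strict p < alpha."""
    m = _universe(discovery, target)
    hit1 = m["P_1"] < alpha
    hit2 = m["P_2"] < alpha
    return OverlapCounts(
        total_genes=len(m),
        x=int(hit1.sum()),
        y=int(hit2.sum()),
        z=int((hit1 & hit2).sum()),
    )


def binomial_tail(z: int, y: int, e: float) -> float:
    """Exact upper tail P(X >= z), X ~ Binomial(y, e), summed in log space."""
    if z <= 0:
        return 1.0
    if z > y:
        return 0.0
    k = np.arange(z, y + 1)
    return float(min(np.exp(logsumexp(stats.binom.logpmf(k, y, e))), 1.0))


def binomial_overlap_test(
    c: OverlapCounts, e_override: float | None = None
) -> OverlapTestResult:
    """One-sided exact binomial test of observed vs expected overlap.

    e defaults to x/total_genes at full precision; ``e_override`` exists to
    reproduce published calls that used a rounded expected proportion.
    """
    if c.y < 1:
        raise ValueError("target set has no hits (y = 0)")
    e = e_override if e_override is not None else c.x / c.total_genes
    if not (0.0 < e < 1.0):
        raise ValueError(f"expected proportion must lie in (0, 1); got {e}")
    return OverlapTestResult(
        e=float(e),
        o_obs=c.z / c.y,
        p_binomial=max(binomial_tail(c.z, c.y, e), _TINY),
    )


def gws_threshold(alpha: float, n_genes: int) -> float:
    """Bonferroni threshold alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's combined probability: -2(ln p1 + ln p2) vs chi-square(4)."""
    if not (0 < p1 <= 1 and 0 < p2 <= 1):
        raise ValueError("P values must lie in (0, 1]")
    X = -2.0 * (np.log(p1) + np.log(p2))
    return float(stats.chi2.sf(X, 4))


def classify_shared_genes(
    t1: pd.DataFrame,
    t2: pd.DataFrame,
    gws: float,
    alpha: float = 0.05,
) -> list[FcpResult]:
    """Per-gene combined-P classification over the shared universe.

    Categories: "1" = trait-1 GWS and trait-2 nominal; "2" = trait-2 GWS
    and trait-1 nominal; "1∩2" (sentinel-shared) = GWS in both; "3" =
    nominal but not GWS in both traits and combined P below the GWS
    threshold; otherwise "none".  Mutually exclusive and exhaustive.
    """
    m = _universe(t1, t2)
    out = []
    for gene, p1, p2 in m.itertuples(index=False):
        p_fcp = fisher_combine(p1, p2)
        gws1, gws2 = p1 < gws, p2 < gws
        nom1, nom2 = p1 < alpha, p2 < alpha
        if gws1 and gws2:
            cat = "1∩2"
        elif gws1 and nom2:
            cat = "1"
        elif gws2 and nom1:
            cat = "2"
        elif nom1 and nom2 and not gws1 and not gws2 and p_fcp < gws:
            cat = "3"
        else:
            cat = "none"
        out.append(FcpResult(gene_id=gene, p1=p1, p2=p2, p_fcp=p_fcp, category=cat))
    return out


def multi_trait_intersection(
    results: dict[str, list[FcpResult]],
    gws: float,
    mode: str = "fcp",
) -> dict[str, set[str]]:
    """Map each gene to the set of trait pairs where it qualifies.

    ``mode='fcp'`` requires p_fcp < gws in a pair; ``mode='category'``
    requires any category other than "none".
    """
    if len(results) < 2:
        raise ValueError("need at least 2 trait pairs")
    gene_pairs: dict[str, set[str]] = {}
    for pair, lst in results.items():
        for r in lst:
            ok = r.p_fcp < gws if mode == "fcp" else r.category != "none"
            if ok:
                gene_pairs.setdefault(r.gene_id, set()).add(pair)
    return gene_pairs


def summary_row(c: OverlapCounts, t: OverlapTestResult) -> dict:
    """One overlap-summary record in the published table layout."""
    return {
        "total_genes": c.total_genes,
        "x": c.x,
        "y": c.y,
        "z": c.z,
        "expected": round(t.e, 3),
        "observed": round(t.o_obs, 3),
        "observed_pct": round(100 * t.o_obs, 1),
        "p_binomial": t.p_binomial,
    }
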