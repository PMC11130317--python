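"""Generators for every input the pipeline consumes.

Two summary-statistic modes:

* moment mode — per-SNP z pairs drawn independently from the bivariate
  normal implied by the LD-score-regression moment structure (fast; used
  for global-correlation and MR calibration; ignores cross-SNP correlation
  of z, so jackknife SEs downstream are approximate);
* effect mode — standardized per-SNP effects drawn block-wise under a
  bivariate polygenic model, with marginal z = sqrt(N) R beta + MVN(0, R)
  noise (real block LD; used for the local-correlation stage).

The sample-overlap intercept term is injected in moment mode only; effect
mode assumes disjoint samples.  LD is AR(1) within non-overlapping blocks:
closed-form positive-definite matrices with unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from crosstrait.globalrg import LdScoreTable
from crosstrait.localrg import Locus
from crosstrait.mr import HarmonizedSet
from crosstrait.sumstats import PairedSumStats, SumStatsTable

_ALLELES = np.array(["A", "C"])  # non-palindromic pair; munge-safe


@dataclass
class LdBlock:
    locus: Locus
    snp_ids: np.ndarray
    positions: np.ndarray
    R: np.ndarray


@dataclass
class LdPanel:
    """Block-diagonal LD reference: AR(1) correlation within each block."""

    blocks: list[LdBlock]

    @property
    def n_snps(self) -> int:
        return sum(len(b.snp_ids) for b in self.blocks)

    @property
    def snp_ids(self) -> np.ndarray:
        return np.concatenate([b.snp_ids for b in self.blocks])

    def loci(self) -> list[Locus]:
        return [b.locus for b in self.blocks]

    def r2_between(self, snp_a: str, snp_b: str) -> float:
        """Squared correlation between two panel SNPs (0 across blocks)."""
        for b in self.blocks:
            ids = list(b.snp_ids)
            if snp_a in ids and snp_b in ids:
                i, j = ids.index(snp_a), ids.index(snp_b)
                return float(b.R[i, j] ** 2)
        return 0.0


@dataclass
class SimPairConfig:
    M: int
    N1: float
    N2: float
    h2_1: float
    h2_2: float
    rg_true: float
    rg_local: dict[int, float] = field(default_factory=dict)
    Ns: float = 0.0
    rho_p: float = 0.0
    seed: int = 0

    @property
    def gcov(self) -> float:
        return self.rg_true * np.sqrt(self.h2_1 * self.h2_2)

    def __post_init__(self) -> None:
        if not (0 <= self.h2_1 <= 1 and 0 <= self.h2_2 <= 1):
            raise ValueError("heritabilities must lie in [0, 1]")
        if abs(self.rg_true) > 1:
            raise ValueError("|rg_true| must be <= 1")


@dataclass
class GeneSimConfig:
    G: int
    pi1: float
    pi2: float
    pi_shared: float
    effect_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pi_shared > min(self.pi1, self.pi2) + 1e-12:
            raise ValueError("pi_shared must be <= min(pi1, pi2)")


@dataclass
class MrSimConfig:
    n_inst: int
    theta: float
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    n_outliers: int = 0
    outlier_shift: float = 0.5
    beta_exp_loc: float = 0.1
    beta_exp_scale: float = 0.05
    se_exp: float = 0.01
    se_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outliers >= self.n_inst:
            raise ValueError("n_outliers must be < n_inst")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


def simulate_ld_panel(
    n_blocks: int,
    block_size: int,
    rho_block,
    seed: int = 0,
    chrom: int = 1,
    spacing: int = 5_000,
) -> LdPanel:
    """AR(1) LD panel: corr(i, j) = rho_block^|i-j| within each block.

    ``rho_block`` may be a scalar (same LD in every block) or a sequence
    cycled across blocks; varying rho across blocks spreads the LD scores,
    which is what identifies the LD-score regression slope downstream.
    """
    rhos = np.broadcast_to(
        np.resize(np.asarray(rho_block, float), n_blocks), (n_blocks,)
    )
    if np.any((rhos < 0) | (rhos >= 1)):
        raise ValueError("rho_block values must lie in [0, 1)")
    idx = np.arange(block_size)
    blocks = []
    snp_counter = 0
    for b in range(n_blocks):
        R = rhos[b] ** np.abs(idx[:, None] - idx[None, :])
        # AR(1) with |rho| < 1 is PD by construction; assert cheaply.
        assert np.all(np.linalg.eigvalsh(R) > 0), "AR(1) block not PD"
        start = b * (block_size + 10) * spacing + 1
        positions = start + idx * spacing
        snp_ids = np.array(
            [f"rs{snp_counter + i + 1}" for i in range(block_size)]
        )
        snp_counter += block_size
        blocks.append(
            LdBlock(
                locus=Locus(
                    locus_id=b + 1,
                    chrom=chrom,
                    start=int(positions[0]),
                    stop=int(positions[-1]),
                ),
                snp_ids=snp_ids,
                positions=positions,
                R=R,
            )
        )
    return LdPanel(blocks=blocks)


def ld_scores(panel: LdPanel) -> LdScoreTable:
    """l_j = sum of r^2 of SNP j with every SNP in its block (incl. itself)."""
    frames = []
    for b in panel.blocks:
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": b.snp_ids,
                    "chrom": b.locus.chrom,
                    "pos": b.positions,
                    "l2": (b.R**2).sum(axis=1),
                }
            )
        )
    return LdScoreTable(pd.concat(frames, ignore_index=True))


def simulate_pair_moment(cfg: SimPairConfig, ld: LdScoreTable) -> PairedSumStats:
    """Draw independent per-SNP z pairs from the LDSC moment structure.

    Var(z1j) = 1 + N1 h2_1 l_j / M; Cov includes the sample-overlap
    intercept Ns rho_p / sqrt(N1 N2).
    """
    rng = np.random.default_rng(cfg.seed)
    df = ld.df
    l = df["l2"].to_numpy(float)
    M = cfg.M
    var1 = 1.0 + cfg.N1 * cfg.h2_1 * l / M
    var2 = 1.0 + cfg.N2 * cfg.h2_2 * l / M
    cov = (
        np.sqrt(cfg.N1 * cfg.N2) * cfg.gcov * l / M
        + cfg.Ns * cfg.rho_p / np.sqrt(cfg.N1 * cfg.N2)
    )
    bad = cov**2 > var1 * var2
    if bad.any():
        j = int(np.argmax(bad))
        raise ValueError(
            f"simulate_pair_moment: non-PSD 2x2 covariance at SNP index {j}"
        )
    x = rng.standard_normal(len(l))
    y = rng.standard_normal(len(l))
    z1 = np.sqrt(var1) * x
    z2 = (cov / np.sqrt(var1)) * x + np.sqrt(var2 - cov**2 / var1) * y
    chrom = df["chrom"].to_numpy(int) if "chrom" in df else np.ones(len(l), int)
    pos = df["pos"].to_numpy(int) if "pos" in df else np.arange(1, len(l) + 1)
    return PairedSumStats(
        snp_id=df["snp_id"].to_numpy(),
        chrom=chrom,
        pos=pos,
        z1=z1,
        z2=z2,
        n1=np.full(len(l), float(cfg.N1)),
        n2=np.full(len(l), float(cfg.N2)),
        label1="trait1",
        label2="trait2",
    )


def simulate_pair_effect(cfg: SimPairConfig, panel: LdPanel) -> PairedSumStats:
    """Draw block-wise standardized effects, then marginal z with block LD.

    Per block the per-SNP effect covariance is [[h2_1, g], [g, h2_2]]/M with
    g the block's genetic covariance (``cfg.rg_local`` overrides the global
    ``rg_true`` per locus id).  z_i = sqrt(N_i) R beta_i + MVN(0, R).
    """
    rng = np.random.default_rng(cfg.seed)
    M = cfg.M
    snp_ids, chroms, poss, z1s, z2s = [], [], [], [], []
    for b in panel.blocks:
        m = len(b.snp_ids)
        rg_b = cfg.rg_local.get(b.locus.locus_id, cfg.rg_true)
        g = rg_b * np.sqrt(cfg.h2_1 * cfg.h2_2)
        C = np.array([[cfg.h2_1, g], [g, cfg.h2_2]]) / M
        if np.linalg.eigvalsh(C).min() < -1e-15:
            raise ValueError(
                f"simulate_pair_effect: non-PSD effect covariance at locus "
                f"{b.locus.locus_id}"
            )
        Lc = np.linalg.cholesky(C + 1e-18 * np.eye(2))
        beta = rng.standard_normal((m, 2)) @ Lc.T
        Lr = np.linalg.cholesky(b.R)
        eps1 = Lr @ rng.standard_normal(m)
        eps2 = Lr @ rng.standard_normal(m)
        z1s.append(np.sqrt(cfg.N1) * b.R @ beta[:, 0] + eps1)
        z2s.append(np.sqrt(cfg.N2) * b.R @ beta[:, 1] + eps2)
        snp_ids.append(b.snp_ids)
        chroms.append(np.full(m, b.locus.chrom))
        poss.append(b.positions)
    n_tot = panel.n_snps
    return PairedSumStats(
        snp_id=np.concatenate(snp_ids),
        chrom=np.concatenate(chroms).astype(int),
        pos=np.concatenate(poss).astype(int),
        z1=np.concatenate(z1s),
        z2=np.concatenate(z2s),
        n1=np.full(n_tot, float(cfg.N1)),
        n2=np.full(n_tot, float(cfg.N2)),
        label1="trait1",
        label2="trait2",
    )


def simulate_gene_pvalues(cfg: GeneSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired per-gene P tables with a configurable shared fraction.

    Associated genes draw -log10(P) ~ Exponential(mean=effect_scale),
    null genes P ~ Uniform(0, 1).  Returns two MAGMA-style frames with
    columns GENE CHR START STOP NSNPS P.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.G
    n_shared = int(round(cfg.pi_shared * G))
    n1_only = int(round(cfg.pi1 * G)) - n_shared
    n2_only = int(round(cfg.pi2 * G)) - n_shared
    if n1_only < 0 or n2_only < 0:
        raise ValueError("pi_shared exceeds a marginal proportion")
    perm = rng.permutation(G)
    shared = perm[:n_shared]
    only1 = perm[n_shared : n_shared + n1_only]
    only2 = perm[n_shared + n1_only : n_shared + n1_only + n2_only]

    def _draw(assoc_idx: np.ndarray) -> np.ndarray:
        p = rng.uniform(size=G)
        neglog = rng.exponential(scale=cfg.effect_scale, size=len(assoc_idx))
        p[assoc_idx] = np.maximum(10.0 ** (-neglog), 1e-300)
        return p

    p1 = _draw(np.concatenate([shared, only1]).astype(int))
    p2 = _draw(np.concatenate([shared, only2]).astype(int))

    starts = np.arange(G) * 100_000 + 1
    base = pd.DataFrame(
        {
            "GENE": [f"GENE{i + 1}" for i in range(G)],
            "CHR": 1,
            "START": starts,
            "STOP": starts + 50_000,
            "NSNPS": rng.integers(5, 200, size=G),
        }
    )
    t1 = base.copy()
    t1["P"] = p1
    t2 = base.copy()
    t2["P"] = p2
    return t1, t2


def simulate_mr_instruments(cfg: MrSimConfig) -> HarmonizedSet:
    """Instrument-level MR dataset with known causal effect and pleiotropy.

    beta_out = theta * beta_exp + alpha + noise; alpha is zero (none),
    zero-mean normal (balanced) or positive-mean (directional); the first
    ``n_outliers`` instruments receive a gross alpha shift.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_inst
    # effect alleles oriented so exposure effects are positive (Egger
    # convention; a random-sign simulation would silently turn directional
    # pleiotropy into balanced pleiotropy after orientation)
    beta_exp_true = np.abs(rng.normal(cfg.beta_exp_loc, cfg.beta_exp_scale, size=n))
    alpha = np.zeros(n)
    if cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, size=n)
    elif cfg.pleiotropy_mode == "directional":
        alpha = rng.normal(cfg.pleiotropy_sd, cfg.pleiotropy_sd / 2.0, size=n)
    if cfg.n_outliers:
        alpha[: cfg.n_outliers] += cfg.outlier_shift
    beta_exp = beta_exp_true + rng.normal(0.0, cfg.se_exp, size=n)
    beta_out = (
        cfg.theta * beta_exp_true + alpha + rng.normal(0.0, cfg.se_out, size=n)
    )
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(n)],
            "beta_exp": beta_exp,
            "se_exp": cfg.se_exp,
            "beta_out": beta_out,
            "se_out": cfg.se_out,
            "eaf_exp": rng.uniform(0.05, 0.95, size=n),
            "eaf_out": np.nan,
        }
    )
    return HarmonizedSet(
        df=df, exposure_label="exposure", outcome_label="outcome", dropped=[]
    )


def simulate_mr_sumstats(
    panel: LdPanel,
    theta_forward: float = 0.1,
    n_inst_a: int = 20,
    n_inst_b: int = 20,
    n_a: float = 200_000,
    n_b: float = 200_000,
    inst_beta: float = 0.05,
    seed: int = 0,
) -> tuple[SumStatsTable, SumStatsTable]:
    """Full summary-stat tables realising one-way causality A -> B.

    One candidate instrument per block is given a large effect in its own
    trait; trait B inherits theta_forward times A's instrument effects,
    trait A shows no effect at B's instruments (no reverse causation).
    Exercises the select -> clump -> harmonize -> estimate path end to end.
    """
    rng = np.random.default_rng(seed)
    blocks = panel.blocks
    if n_inst_a + n_inst_b > len(blocks):
        raise ValueError("need at least one block per instrument")
    order = rng.permutation(len(blocks))
    a_blocks = set(order[:n_inst_a])
    b_blocks = set(order[n_inst_a : n_inst_a + n_inst_b])

    rows_a, rows_b = [], []
    from scipy import stats as _st

    for bi, block in enumerate(blocks):
        for si, (sid, pos) in enumerate(zip(block.snp_ids, block.positions)):
            is_a_inst = bi in a_blocks and si == 0
            is_b_inst = bi in b_blocks and si == 0
            se_a = 1.0 / np.sqrt(n_a)
            se_b = 1.0 / np.sqrt(n_b)
            beta_a_true = inst_beta * rng.choice([-1, 1]) if is_a_inst else 0.0
            beta_b_true = inst_beta * rng.choice([-1, 1]) if is_b_inst else 0.0
            beta_b_true += theta_forward * beta_a_true
            beta_a = beta_a_true + rng.normal(0, se_a)
            beta_b = beta_b_true + rng.normal(0, se_b)
            pa = float(2 * _st.norm.sf(abs(beta_a / se_a)))
            pb = float(2 * _st.norm.sf(abs(beta_b / se_b)))
            eaf = rng.uniform(0.1, 0.9)
            rows_a.append(
                (sid, block.locus.chrom, pos, "A", "C", beta_a, se_a,
                 max(pa, 1e-300), n_a, eaf)
            )
            rows_b.append(
                (sid, block.locus.chrom, pos, "A", "C", beta_b, se_b,
                 max(pb, 1e-300), n_b, eaf)
            )
    cols = ["snp_id", "chrom", "pos", "a1", "a2", "beta", "se", "p", "n", "eaf"]
    ta = SumStatsTable(pd.DataFrame(rows_a, columns=cols), trait_label="traitA")
    tb = SumStatsTable(pd.DataFrame(rows_b, columns=cols), trait_label="traitB")
    return ta, tb


# ---------------------------------------------------------------------------
# file emission (all plain text)

def write_locus_file(loci: list[Locus], path) -> None:
    pd.DataFrame(
        [
            {"LOC": x.locus_id, "CHR": x.chrom, "START": x.start, "STOP": x.stop}
            for x in loci
        ]
    ).to_csv(path, sep="\t", index=False)


def write_pair_sumstats(pair: PairedSumStats, path1, path2, seed=None) -> None:
    """Write both traits of a paired simulation in munged layout."""
    for path, z, n in ((path1, pair.z1, pair.n1), (path2, pair.z2, pair.n2)):
        from scipy import stats as _st

        p = 2 * _st.norm.sf(np.abs(z))
        df = pd.DataFrame(
            {
                "SNP": pair.snp_id,
                "CHR": pair.chrom,
                "BP": pair.pos,
                "A1": "A",
                "A2": "C",
                "Z": z,
                "N": n,
                "P": np.maximum(p, 1e-300),
            }
        )
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            df.to_csv(fh, sep="\t", index=False)


def write_truth(cfg, path) -> None:
    """Record the generative parameters of a run as YAML."""
    d = {k: v for k, v in vars(cfg).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
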