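"""Reading, quality control and harmonisation of GWAS summary statistics.

All coordinates are GRCh37, 1-based, inclusive at both ends.  Effect sizes
are kept on the log scale throughout: odds ratios are converted to ln(OR)
at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Strand-ambiguous allele pairs (cannot be resolved without frequencies).
PALINDROMIC = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: Canonical column names and their common aliases in published sumstats.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "snp_id": ("SNP", "snp", "rsid", "RSID", "MarkerName", "variant_id", "ID"),
    "chrom": ("CHR", "chr", "chromosome", "CHROM", "#CHROM"),
    "pos": ("BP", "bp", "POS", "pos", "position", "base_pair_location"),
    "a1": ("A1", "a1", "effect_allele", "EA", "ALT"),
    "a2": ("A2", "a2", "other_allele", "OA", "NEA", "REF"),
    "beta": ("BETA", "beta", "b", "Effect", "effect"),
    "or_": ("OR", "or", "odds_ratio"),
    "z": ("Z", "z", "zscore", "Zscore"),
    "se": ("SE", "se", "StdErr", "standard_error"),
    "p": ("P", "p", "pval", "P-value", "PVAL", "p_value"),
    "n": ("N", "n", "sample_size", "Neff"),
    "eaf": ("EAF", "eaf", "FRQ", "frq", "effect_allele_frequency", "MAF"),
}

MANDATORY = ("snp_id", "chrom", "pos", "a1", "a2", "se", "p")


class SumStatsError(ValueError):
    """Fatal condition while reading or filtering summary statistics."""


@dataclass(frozen=True)
class Region:
    """A genomic interval, 1-based and inclusive at both ends."""

    chrom: int
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"Region start {self.start} > stop {self.stop}")

    def contains(self, chrom, pos) -> np.ndarray:
        """Vectorised membership test."""
        return (np.asarray(chrom) == self.chrom) & (
            (np.asarray(pos) >= self.start) & (np.asarray(pos) <= self.stop)
        )


#: MHC, GRCh37 (NCBI GRC region definition).
MHC = Region(6, 28477797, 33448354)
#: The commonly used extended MHC exclusion, approx. 25-34 Mb.
MHC_EXTENDED = Region(6, 25_000_000, 34_000_000)


@dataclass
class SumStatsTable:
    """Per-variant GWAS summary records, sorted by (chrom, pos).

    ``df`` columns: snp_id, chrom, pos, a1, a2, beta, se, p, n, eaf
    (eaf may be NaN).  ``log`` accumulates per-filter attrition counts.
    """

    df: pd.DataFrame
    trait_label: str = ""
    genome_build: str = "GRCh37"
    log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def _replace(self, df: pd.DataFrame, **extra_log: int) -> "SumStatsTable":
        log = dict(self.log)
        for k, v in extra_log.items():
            log[k] = log.get(k, 0) + v
        return SumStatsTable(
            df=df.reset_index(drop=True),
            trait_label=self.trait_label,
            genome_build=self.genome_build,
            log=log,
        )

    @property
    def z(self) -> np.ndarray:
        return (self.df["beta"] / self.df["se"]).to_numpy(float)


def _resolve_columns(columns, dialect):
    """Map canonical field -> actual column name, honouring a user dialect."""
    resolved = {}
    for canon, aliases in DEFAULT_ALIASES.items():
        if dialect and canon in dialect:
            if dialect[canon] in columns:
                resolved[canon] = dialect[canon]
            continue
        for alias in aliases:
            if alias in columns:
                resolved[canon] = alias
                break
    return resolved


def read_sumstats(
    path,
    dialect: dict[str, str] | None = None,
    n_default: float | None = None,
    trait_label: str = "",
) -> SumStatsTable:
    """Read whitespace/tab-delimited summary statistics with a header row.

    ``dialect`` maps canonical names (``snp_id``, ``chrom``, ``pos``, ``a1``,
    ``a2``, ``beta`` or ``or_``, ``se``, ``p``, ``n``, ``eaf``) to the file's
    column names; common aliases are recognised automatically.  If the file
    carries an odds-ratio column instead of beta, beta = ln(OR).  Rows
    violating the per-variant invariants (non-ACGT or identical alleles,
    se <= 0, p outside (0, 1], non-finite z) are dropped and counted.

    A missing sample-size column is permitted when ``n_default`` supplies a
    per-file constant N.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    if raw.empty:
        raise SumStatsError(f"{path}: no rows")
    cols = _resolve_columns(raw.columns, dialect)

    # signed-Z files carry no beta/se; read them as beta = Z with unit SE
    z_mode = (
        "z" in cols and "beta" not in cols and "or_" not in cols
    )
    mandatory = [c for c in MANDATORY if not (z_mode and c == "se")]
    missing = [c for c in mandatory if c not in cols]
    if missing:
        raise SumStatsError(f"{path}: missing mandatory column(s): {missing}")
    if "beta" not in cols and "or_" not in cols and not z_mode:
        raise SumStatsError(f"{path}: need an effect column (beta, OR or Z)")
    if "n" not in cols and n_default is None:
        raise SumStatsError(f"{path}: no N column and no n_default supplied")

    df = pd.DataFrame({"snp_id": raw[cols["snp_id"]].astype(str)})
    df["chrom"] = pd.to_numeric(raw[cols["chrom"]], errors="coerce")
    df["pos"] = pd.to_numeric(raw[cols["pos"]], errors="coerce")
    df["a1"] = raw[cols["a1"]].astype(str).str.upper()
    df["a2"] = raw[cols["a2"]].astype(str).str.upper()
    if z_mode:
        df["beta"] = pd.to_numeric(raw[cols["z"]], errors="coerce")
        df["se"] = 1.0
    elif "beta" in cols:
        df["beta"] = pd.to_numeric(raw[cols["beta"]], errors="coerce")
        df["se"] = pd.to_numeric(raw[cols["se"]], errors="coerce")
    else:
        or_ = pd.to_numeric(raw[cols["or_"]], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            df["beta"] = np.log(or_.where(or_ > 0))
        df["se"] = pd.to_numeric(raw[cols["se"]], errors="coerce")
    df["p"] = pd.to_numeric(raw[cols["p"]], errors="coerce")
    if "n" in cols:
        df["n"] = pd.to_numeric(raw[cols["n"]], errors="coerce")
    else:
        df["n"] = float(n_default)
    if "eaf" in cols:
        df["eaf"] = pd.to_numeric(raw[cols["eaf"]], errors="coerce")
    else:
        df["eaf"] = np.nan

    ok = (
        df[["chrom", "pos", "beta", "se", "p", "n"]].notna().all(axis=1)
        & (df["se"] > 0)
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & (df["n"] > 0)
        & np.isfinite(df["beta"] / df["se"].where(df["se"] > 0))
    )
    n_bad = int((~ok).sum())
    df = df[ok].copy()
    if df.empty:
        raise SumStatsError(f"{path}: zero parsable rows ({n_bad} rejected)")
    df["chrom"] = df["chrom"].astype(int)
    df["pos"] = df["pos"].astype(int)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if n_bad:
        logger.info("%s: dropped %d unparsable/invalid rows", path, n_bad)
    return SumStatsTable(
        df=df, trait_label=trait_label, log={"read_rejected": n_bad}
    )


def munge(
    t: SumStatsTable, reference_snps: set[str] | frozenset[str] | None = None
) -> SumStatsTable:
    """QC filter: duplicates, strand-ambiguous and non-SNP variants.

    All copies of a duplicated snp_id are removed (we cannot adjudicate
    which record is correct).  Palindromic (A/T, C/G) variants are always
    removed here; the MR module applies its own frequency-aware rule at
    harmonisation instead.  With a non-empty ``reference_snps`` the output
    is restricted to that set (e.g. HapMap3).  Idempotent.
    """
    if len(t) == 0:
        raise SumStatsError("munge: empty input table")
    df = t.df

    is_snp = (
        df["a1"].isin(list(VALID_ALLELES))
        & df["a2"].isin(list(VALID_ALLELES))
        & (df["a1"] != df["a2"])
    )
    n_nonsnp = int((~is_snp).sum())
    df = df[is_snp]

    pal = pd.Series(
        [(x, y) in PALINDROMIC for x, y in zip(df["a1"], df["a2"])],
        index=df.index,
    )
    n_pal = int(pal.sum())
    df = df[~pal]

    dup = df["snp_id"].duplicated(keep=False)
    n_dup = int(dup.sum())
    df = df[~dup]

    n_ref = 0
    if reference_snps:
        in_ref = df["snp_id"].isin(reference_snps)
        n_ref = int((~in_ref).sum())
        df = df[in_ref]

    if df.empty:
        raise SumStatsError(
            "munge: no variants survive "
            f"(non-SNP {n_nonsnp}, palindromic {n_pal}, duplicate {n_dup}, "
            f"off-reference {n_ref})"
        )
    return t._replace(
        df,
        munge_nonsnp=n_nonsnp,
        munge_palindromic=n_pal,
        munge_duplicate=n_dup,
        munge_off_reference=n_ref,
    )


def exclude_region(t: SumStatsTable, r: Region) -> SumStatsTable:
    """Drop variants inside ``r`` (boundaries inclusive)."""
    inside = r.contains(t.df["chrom"].to_numpy(), t.df["pos"].to_numpy())
    n_in = int(inside.sum())
    return t._replace(t.df[~inside], region_excluded=n_in)


@dataclass
class PairedSumStats:
    """Two traits aligned on the same variants in the same order.

    ``z2`` is sign-flipped wherever trait 2's alleles were swapped relative
    to trait 1's orientation.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    label1: str = ""
    label2: str = ""
    n_dropped_alleles: int = 0

    def __len__(self) -> int:
        return len(self.snp_id)


def align_pair(a: SumStatsTable, b: SumStatsTable) -> PairedSumStats:
    """Intersect two munged tables and align trait 2 to trait 1's alleles.

    Where b's (a1, a2) equal a's (a2, a1) the z of b is negated; variants
    whose allele sets differ between the tables are dropped and counted.
    """
    m = a.df.merge(b.df, on="snp_id", suffixes=("_1", "_2"), how="inner")
    if m.empty:
        raise SumStatsError("align_pair: no shared variants")
    same = (m["a1_1"] == m["a1_2"]) & (m["a2_1"] == m["a2_2"])
    swapped = (m["a1_1"] == m["a2_2"]) & (m["a2_1"] == m["a1_2"])
    keep = same | swapped
    n_drop = int((~keep).sum())
    m = m[keep]
    if m.empty:
        raise SumStatsError("align_pair: no allele-compatible shared variants")
    m = m.sort_values(["chrom_1", "pos_1"], kind="mergesort")
    sign = np.where(
        (m["a1_1"] == m["a2_2"]) & (m["a2_1"] == m["a1_2"]), -1.0, 1.0
    )
    return PairedSumStats(
        snp_id=m["snp_id"].to_numpy(),
        chrom=m["chrom_1"].to_numpy(int),
        pos=m["pos_1"].to_numpy(int),
        z1=(m["beta_1"] / m["se_1"]).to_numpy(float),
        z2=sign * (m["beta_2"] / m["se_2"]).to_numpy(float),
        n1=m["n_1"].to_numpy(float),
        n2=m["n_2"].to_numpy(float),
        label1=a.trait_label,
        label2=b.trait_label,
        n_dropped_alleles=n_drop,
    )


def write_munged(t: SumStatsTable, path) -> None:
    """Write the fixed munged layout: SNP CHR BP A1 A2 Z N P."""
    out = pd.DataFrame(
        {
            "SNP": t.df["snp_id"],
            "CHR": t.df["chrom"],
            "BP": t.df["pos"],
            "A1": t.df["a1"],
            "A2": t.df["a2"],
            "Z": t.z,
            "N": t.df["n"],
            "P": t.df["p"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
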