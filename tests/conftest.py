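import numpy as np
import pandas as pd
import pytest

from crosstrait.sumstats import SumStatsTable

SUMSTATS_COLS = ["snp_id", "chrom", "pos", "a1", "a2", "beta", "se", "p", "n", "eaf"]


def make_table(rows, trait_label="trait"):
    """Build a SumStatsTable from (snp, chr, pos, a1, a2, beta, se, p, n[, eaf])."""
    recs = []
    for r in rows:
        r = list(r)
        if len(r) == 9:
            r.append(np.nan)
        recs.append(dict(zip(SUMSTATS_COLS, r)))
    df = pd.DataFrame(recs)
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return SumStatsTable(df=df, trait_label=trait_label)


@pytest.fixture
def small_table():
    return make_table(
        [
            ("rs1", 1, 1000, "A", "G", 0.10, 0.02, 1e-7, 10000, 0.3),
            ("rs2", 1, 2000, "C", "T", -0.05, 0.02, 1e-3, 10000, 0.6),
            ("rs3", 2, 1500, "G", "A", 0.02, 0.02, 0.4, 10000, 0.1),
        ]
    )


def write_sumstats_file(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
    return path
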