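"""Per-CpG bisulfite call tables: loading, filtering and genome summaries.

A :class:`SiteTable` holds one record per CpG dyad, keyed at the 0-based
position of the plus-strand cytosine, with per-strand methylated/total read
counts retained so the per-strand coverage filter is exact.  The per-site
methylation fraction pools both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_COLUMNS = ["contig", "pos", "meth_plus", "total_plus", "meth_minus", "total_minus"]


class SiteTableError(ValueError):
    pass


class SiteTable:
    """Ordered per-dyad methylation counts with pooled-strand fractions."""

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise SiteTableError(f"missing columns: {missing}")
        df = frame.loc[:, _COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        for c in _COLUMNS[2:]:
            df[c] = df[c].astype(np.int64)
            if (df[c] < 0).any():
                raise SiteTableError(f"negative counts in {c}")
        if (df["meth_plus"] > df["total_plus"]).any() or (
            df["meth_minus"] > df["total_minus"]
        ).any():
            raise SiteTableError("methylated count exceeds total count")
        df = df.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=["contig", "pos"])
        if dup.any():
            raise SiteTableError("duplicate (contig, pos) records")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def totals(self) -> np.ndarray:
        return (self.frame["total_plus"] + self.frame["total_minus"]).to_numpy()

    def fractions(self) -> np.ndarray:
        """Pooled-strand methylation fraction per dyad (NaN where uncovered)."""
        tot = self.totals.astype(float)
        meth = (self.frame["meth_plus"] + self.frame["meth_minus"]).to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, meth / tot, np.nan)

    def by_contig(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """contig -> (positions, fractions), positions strictly increasing."""
        frac = self.fractions()
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        pos = self.frame["pos"].to_numpy()
        for contig, idx in self.frame.groupby("contig", sort=True).indices.items():
            out[str(contig)] = (pos[idx], frac[idx])
        return out


def read_site_table(path, dialect: str = "cytosine_report") -> SiteTable:
    """Read per-cytosine calls and merge dyad strand rows.

    ``cytosine_report``: Bismark-style TSV (chrom, 1-based pos, strand,
    count_methylated, count_unmethylated, context[, trinucleotide]); the two
    rows of a dyad (plus at p, minus at p+1) merge into one record keyed at
    the 0-based plus-strand position.  A dyad seen on only one strand keeps
    zero counts on the missing strand.

    ``methylextract_like``: headered dyad-level TSV with columns
    contig, pos (1-based plus-strand C), meth_plus, total_plus, meth_minus,
    total_minus.
    """
    if dialect == "methylextract_like":
        df = pd.read_csv(path, sep="\t")
        df["pos"] = df["pos"] - 1
        return SiteTable(df)
    if dialect != "cytosine_report":
        raise SiteTableError(f"unknown dialect {dialect!r}")

    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 3, 4, 5],
            names=["contig", "pos", "strand", "meth", "unmeth", "context"],
            dtype={0: str, 2: str, 5: str},
        )
    except pd.errors.EmptyDataError:
        return SiteTable(pd.DataFrame(columns=_COLUMNS))
    bad_ctx = ~df["context"].isin(["CpG", "CG"])
    if bad_ctx.any():
        warnings.warn(
            f"{int(bad_ctx.sum())} rows with non-CpG context labels", stacklevel=2
        )
    plus = df[df["strand"] == "+"].copy()
    minus = df[df["strand"] == "-"].copy()
    # 0-based dyad key: plus-strand C at file pos p -> p-1; minus-strand C at p -> p-2
    plus["key"] = plus["pos"] - 1
    minus["key"] = minus["pos"] - 2
    p = plus.groupby(["contig", "key"], sort=False)[["meth", "unmeth"]].sum()
    m = minus.groupby(["contig", "key"], sort=False)[["meth", "unmeth"]].sum()
    merged = p.join(m, how="outer", lsuffix="_p", rsuffix="_m").fillna(0).reset_index()
    out = pd.DataFrame(
        {
            "contig": merged["contig"],
            "pos": merged["key"],
            "meth_plus": merged["meth_p"],
            "total_plus": merged["meth_p"] + merged["unmeth_p"],
            "meth_minus": merged["meth_m"],
            "total_minus": merged["meth_m"] + merged["unmeth_m"],
        }
    )
    return SiteTable(out)


def write_cytosine_report(table: SiteTable, path) -> None:
    """Write Bismark-style per-cytosine rows (two per dyad, 1-based)."""
    with open(path, "w") as fh:
        for row in table.frame.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{row.pos + 1}\t+\t{row.meth_plus}\t"
                f"{row.total_plus - row.meth_plus}\tCpG\tCGN\n"
            )
            fh.write(
                f"{row.contig}\t{row.pos + 2}\t-\t{row.meth_minus}\t"
                f"{row.total_minus - row.meth_minus}\tCpG\tCGN\n"
            )


def write_fractions_bedgraph(table: SiteTable, path) -> None:
    frac = table.fractions()
    with open(path, "w") as fh:
        for (row, f) in zip(table.frame.itertuples(index=False), frac):
            if np.isnan(f):
                continue
            fh.write(f"{row.contig}\t{row.pos}\t{row.pos + 2}\t{f:.6g}\n")


def filter_sites(table: SiteTable, min_per_strand: int = 10) -> SiteTable:
    """Keep dyads with at least ``min_per_strand`` reads on each strand."""
    if min_per_strand < 0:
        raise SiteTableError("min_per_strand must be >= 0")
    df = table.frame
    keep = (df["total_plus"] >= min_per_strand) & (df["total_minus"] >= min_per_strand)
    return SiteTable(df[keep].reset_index(drop=True))


@dataclass(frozen=True)
class NonconversionEstimate:
    rate: float
    ci_low: float
    ci_high: float
    n_meth: int
    n_total: int


def estimate_nonconversion(spike_table: SiteTable, alpha: float = 0.05) -> NonconversionEstimate:
    """Pooled non-conversion rate from an unmethylated spike-in, with
    Clopper-Pearson confidence interval."""
    if len(spike_table) == 0:
        raise SiteTableError("empty spike-in table")
    df = spike_table.frame
    k = int((df["meth_plus"] + df["meth_minus"]).sum())
    n = int((df["total_plus"] + df["total_minus"]).sum())
    if n == 0:
        raise SiteTableError("spike-in has zero total reads")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return NonconversionEstimate(k / n, lo, hi, k, n)


@dataclass(frozen=True)
class GlobalMethylation:
    percent: float
    caller: str
    n_sites: int
    n_called: int | None = None
    calls: np.ndarray | None = None


def genomewide_methylation(
    table: SiteTable,
    caller: str = "binomial_vs_spike",
    nonconversion: float | None = None,
    q: float = 0.05,
) -> GlobalMethylation:
    """Genome-wide percent methylation.

    ``mean_fraction``: 100 * mean per-site pooled fraction.
    ``binomial_vs_spike``: per-site one-sided binomial test of the pooled
    counts against the spike-in non-conversion rate, Benjamini-Hochberg at
    ``q``; percent = 100 * called / tested.
    """
    if len(table) == 0:
        raise SiteTableError("empty site table")
    if caller == "mean_fraction":
        frac = table.fractions()
        return GlobalMethylation(100.0 * float(np.nanmean(frac)), caller, len(table))
    if caller != "binomial_vs_spike":
        raise SiteTableError(f"unknown caller {caller!r}")
    if nonconversion is None:
        raise SiteTableError("binomial_vs_spike requires a nonconversion rate")
    df = table.frame
    k = (df["meth_plus"] + df["meth_minus"]).to_numpy()
    n = (df["total_plus"] + df["total_minus"]).to_numpy()
    tested = n > 0
    pvals = stats.binom.sf(k[tested] - 1, n[tested], nonconversion)
    padj = stats.false_discovery_control(pvals, method="bh")
    called = padj <= q
    calls = np.zeros(len(df), dtype=bool)
    calls[np.flatnonzero(tested)] = called
    pct = 100.0 * called.sum() / tested.sum()
    return GlobalMethylation(float(pct), caller, int(tested.sum()), int(called.sum()), calls)


@dataclass(frozen=True)
class SpikeComparison:
    difference: float
    z: float
    p: float


def compare_to_spikein(table: SiteTable, spike_table: SiteTable) -> SpikeComparison:
    """Two-proportion z-test of pooled methylation: sample vs spike-in."""
    if len(table) == 0 or len(spike_table) == 0:
        raise SiteTableError("both tables must be nonempty")

    def _pool(t: SiteTable) -> tuple[int, int]:
        df = t.frame
        return (
            int((df["meth_plus"] + df["meth_minus"]).sum()),
            int((df["total_plus"] + df["total_minus"]).sum()),
        )

    k1, n1 = _pool(table)
    k2, n2 = _pool(spike_table)
    if n1 == 0 or n2 == 0:
        raise SiteTableError("zero total reads")
    p1, p2 = k1 / n1, k2 / n2
    pbar = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return SpikeComparison(p1 - p2, float(z), float(min(1.0, p)))
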