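"""Expression quantification and methylation-expression integration:
FPKM, top/bottom expression groups, promoter-methylation bins, tissue CV,
within-species z-score coupling, housekeeping enrichment, orthogroup
methylation ranking and the single/multi-exon contrast."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .features import FeatureMethylation


def fpkm(
    counts: pd.DataFrame,
    feature_lengths: Mapping[str, float] | pd.Series,
    total_mapped: Mapping[str, float] | pd.Series | float,
) -> pd.DataFrame:
    """count / (length_kb * mapped_millions), per gene x sample."""
    lengths = pd.Series(feature_lengths).reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing feature lengths for some genes")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")
    if np.isscalar(total_mapped):
        totals = pd.Series(float(total_mapped), index=counts.columns)
    else:
        totals = pd.Series(total_mapped).reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("total mapped reads must be > 0 for every sample")
    out = counts.div(lengths / 1000.0, axis=0).div(totals / 1e6, axis=1)
    return out


def expression_groups(expr: pd.DataFrame, q: float = 0.2) -> tuple[list[str], list[str]]:
    """(high, low) gene sets: top/bottom ``q`` fraction by mean expression,
    ties broken by stable gene-id order."""
    if len(expr) < 5:
        raise ValueError("need at least 5 genes")
    means = expr.mean(axis=1)
    if means.nunique() == 1:
        warnings.warn("all mean expressions identical; grouping by id order", stacklevel=2)
    order = means.sort_values(kind="mergesort").index  # ascending, stable
    k = int(round(q * len(order)))
    low = sorted(order[:k])
    high = sorted(order[len(order) - k :])
    return high, low


@dataclass(frozen=True)
class BinnedExpression:
    bin_edges: np.ndarray
    medians: np.ndarray
    counts: np.ndarray
    h: float
    p: float


def upstream_meth_expression(
    upstream_meth: Mapping[str, float] | pd.Series,
    expr: pd.DataFrame,
    n_bins: int = 5,
) -> BinnedExpression:
    """Genes binned by upstream-methylation quantiles; per-bin median mean
    expression and a Kruskal-Wallis test across bins."""
    meth = pd.Series(upstream_meth).dropna()
    means = expr.mean(axis=1)
    shared = meth.index.intersection(means.index)
    meth = meth.loc[shared]
    ex = means.loc[shared]
    qs = np.quantile(meth, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(qs[1:-1], meth, side="right"), 0, n_bins - 1)
    groups = [ex.to_numpy()[bins == b] for b in range(n_bins)]
    populated = [g for g in groups if len(g) > 0]
    if len(populated) < 2:
        raise ValueError("fewer than 2 populated methylation bins")
    h, p = stats.kruskal(*populated)
    medians = np.array([np.median(g) if len(g) else np.nan for g in groups])
    counts = np.array([len(g) for g in groups])
    return BinnedExpression(qs, medians, counts, float(h), float(p))


def tissue_cv(expr: pd.DataFrame, tissues: Mapping[str, str] | None = None) -> pd.Series:
    """Per-gene coefficient of variation (sample sd / mean) across tissue
    samples; genes with zero mean are undefined (NaN).  When several samples
    share a tissue label they are averaged per tissue first."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = expr
    if tissues is not None:
        mat = expr.T.groupby(pd.Series(tissues)).mean().T
        if mat.shape[1] < 2:
            raise ValueError("need at least 2 tissues")
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    cv.name = "cv"
    return cv


@dataclass(frozen=True)
class CvContrast:
    median_high: float
    median_low: float
    u: float
    p: float


def cv_contrast(cv: pd.Series, high_genes: Iterable[str], low_genes: Iterable[str]) -> CvContrast:
    """Median CV in high- vs low-methylation gene groups + Mann-Whitney p."""
    hi = cv.reindex(list(high_genes)).dropna()
    lo = cv.reindex(list(low_genes)).dropna()
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("empty group after dropping undefined CVs")
    u, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
    return CvContrast(float(hi.median()), float(lo.median()), float(u), float(p))


def zscore_coupling(per_species: pd.DataFrame) -> pd.DataFrame:
    """Within-species z-scores of methylation and expression, pooled.

    ``per_species`` columns: species, gene, meth, expr (and optionally
    ``conserved``).  Returns the input plus z_meth / z_expr columns; the
    z-transform is computed within each species so pooling preserves the
    per-species standardization.
    """
    req = {"species", "gene", "meth", "expr"}
    if not req.issubset(per_species.columns):
        raise ValueError(f"need columns {sorted(req)}")
    out = per_species.copy()
    for col, zcol in (("meth", "z_meth"), ("expr", "z_expr")):
        def _z(s: pd.Series) -> pd.Series:
            sd = s.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"zero {col} variance within a species")
            return (s - s.mean()) / sd
        out[zcol] = out.groupby("species", group_keys=False)[col].apply(_z)
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    table: np.ndarray  # rows: (top, bottom) x cols: (housekeeping, other)
    odds_ratio: float
    p: float


def _conditional_ml_or(table: np.ndarray) -> float:
    """Conditional maximum-likelihood odds ratio of a 2x2 table (the
    noncentral hypergeometric MLE, as in R's fisher.test)."""
    a, b = table[0]
    c, d = table[1]
    n1, n2, k = a + b, c + d, a + c
    if a == 0 or d == 0:
        return 0.0
    if b == 0 or c == 0:
        return np.inf

    def nll(log_or: float) -> float:
        return -stats.nchypergeom_fisher.logpmf(a, n1 + n2, n1, k, np.exp(log_or))

    res = minimize_scalar(nll, bounds=(-15, 15), method="bounded")
    return float(np.exp(res.x))


def housekeeping_enrichment(
    top_genes: Iterable[str],
    bottom_genes: Iterable[str],
    housekeeping: Iterable[str],
) -> EnrichmentResult:
    """Fisher exact test of housekeeping membership in the top vs bottom
    methylation groups, with the conditional-ML odds ratio."""
    hk = set(housekeeping)
    top = list(top_genes)
    bot = list(bottom_genes)
    a = sum(g in hk for g in top)
    b = len(top) - a
    c = sum(g in hk for g in bot)
    d = len(bot) - c
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise ValueError("empty margin in 2x2 table")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(table, _conditional_ml_or(table), float(p))


@dataclass(frozen=True)
class OrthogroupMethylation:
    scores: pd.Series  # orthogroup -> mean within-species z, ranked descending
    top: list[str]
    bottom: list[str]


def orthogroup_methylation(
    meth_by_species: pd.DataFrame,
    orthomap: pd.DataFrame,
    conserved_only: bool = True,
    q: float = 0.2,
) -> OrthogroupMethylation:
    """Orthogroup score = mean over species of within-species z-scored gene
    methylation, paralogs averaged within species first; ranked descending
    with top/bottom ``q`` sets.

    ``meth_by_species`` columns: species, gene, meth.
    ``orthomap`` columns: orthogroup, species, gene.
    """
    for frame, req in ((meth_by_species, {"species", "gene", "meth"}),
                       (orthomap, {"orthogroup", "species", "gene"})):
        if not req.issubset(frame.columns):
            raise ValueError(f"need columns {sorted(req)}")
    if orthomap.duplicated(subset=["species", "gene"]).any():
        raise ValueError("a gene belongs to more than one orthogroup")
    z = meth_by_species.copy()
    z["z"] = z.groupby("species")["meth"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=1)
    )
    merged = orthomap.merge(z[["species", "gene", "z"]], on=["species", "gene"], how="left")
    n_species = merged["species"].nunique()
    per_sp = (
        merged.dropna(subset=["z"])
        .groupby(["orthogroup", "species"])["z"]
        .mean()
        .reset_index()
    )
    counts = per_sp.groupby("orthogroup")["species"].nunique()
    scores = per_sp.groupby("orthogroup")["z"].mean()
    if conserved_only:
        keep = counts[counts == n_species].index
        if len(keep) == 0:
            raise ValueError("no orthogroup present in all species")
        scores = scores.loc[keep]
    scores = scores.sort_values(ascending=False, kind="mergesort")
    k = max(1, int(round(q * len(scores))))
    return OrthogroupMethylation(scores, list(scores.index[:k]), list(scores.index[-k:]))


@dataclass(frozen=True)
class ExonCountContrast:
    mean_single: float | None
    mean_multi: float | None
    u: float | None
    p: float | None


def exon_count_contrast(
    gene_meths: Mapping[str, float] | pd.Series,
    exon_counts: Mapping[str, int] | pd.Series,
) -> ExonCountContrast:
    """Mean methylation of 1-exon vs multi-exon genes + Mann-Whitney test;
    an empty group is reported as undefined rather than an error."""
    meth = pd.Series(gene_meths).dropna()
    counts = pd.Series(exon_counts).reindex(meth.index).dropna()
    meth = meth.loc[counts.index]
    single = meth[counts == 1]
    multi = meth[counts >= 2]
    ms = float(single.mean()) if len(single) else None
    mm = float(multi.mean()) if len(multi) else None
    if len(single) == 0 or len(multi) == 0:
        warnings.warn("one exon-count group is empty; test undefined", stacklevel=2)
        return ExonCountContrast(ms, mm, None, None)
    u, p = stats.mannwhitneyu(single, multi, alternative="two-sided")
    return ExonCountContrast(ms, mm, float(u), float(p))


def gene_exon_counts(gene_exons: Mapping[str, Sequence]) -> pd.Series:
    return pd.Series({g: len(ex) for g, ex in gene_exons.items()}, name="n_exons")


def gene_mean_from_features(feature_meths: Sequence[FeatureMethylation]) -> pd.Series:
    """Per-gene mean of defined feature means, grouped by parent gene."""
    acc: dict[str, list[float]] = {}
    for fm in feature_meths:
        if fm.defined and fm.feature.parent:
            acc.setdefault(fm.feature.parent, []).append(fm.mean_methylation)
    return pd.Series({g: float(np.mean(v)) for g, v in acc.items()}, name="meth")
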