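"""Feature-level methylation: per-feature means, class summaries with
bootstrap CIs, high/low clustering, metagene and exon-rank profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import logit

from .annotation import GenomeAnnotation, Interval
from .sites import SiteTable


@dataclass(frozen=True)
class FeatureMethylation:
    """Mean methylation of covered CpGs in one feature; undefined below the
    minimum-CpG rule."""

    feature: Interval
    n_covered_cpgs: int
    mean_methylation: float | None

    @property
    def defined(self) -> bool:
        return self.mean_methylation is not None


def feature_mean_methylation(
    features: Sequence[Interval],
    sites: SiteTable,
    min_cpgs: int = 3,
) -> list[FeatureMethylation]:
    """Mean of per-site fractions over covered CpGs inside each feature.

    Features with fewer than ``min_cpgs`` covered CpGs are reported with an
    undefined mean; ``sites`` is expected to be coverage-filtered already.
    """
    by_contig = sites.by_contig()
    out: list[FeatureMethylation] = []
    for iv in features:
        got = by_contig.get(iv.contig)
        if got is None:
            out.append(FeatureMethylation(iv, 0, None))
            continue
        pos, frac = got
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        vals = frac[lo:hi]
        vals = vals[~np.isnan(vals)]
        n = len(vals)
        mean = float(vals.mean()) if n >= min_cpgs else None
        out.append(FeatureMethylation(iv, n, mean))
    return out


@dataclass(frozen=True)
class ClassSummary:
    mean: float
    ci_low: float
    ci_high: float
    n_features: int


def class_summary(
    feature_meths: Iterable[FeatureMethylation],
    n_boot: int = 1000,
    seed: int = 0,
) -> ClassSummary:
    """Point estimate and percentile bootstrap CI of the class mean,
    resampling features with replacement."""
    vals = np.array([f.mean_methylation for f in feature_meths if f.defined], float)
    if len(vals) == 0:
        raise ValueError("no defined features in class")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    boots = vals[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ClassSummary(float(vals.mean()), float(lo), float(hi), len(vals))


def background_mean(background: Sequence[Interval], sites: SiteTable) -> float:
    """Mean methylation over all CpGs inside the background intervals (no
    feature-level aggregation)."""
    by_contig = sites.by_contig()
    acc: list[np.ndarray] = []
    for iv in background:
        got = by_contig.get(iv.contig)
        if got is None:
            continue
        pos, frac = got
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        acc.append(frac[lo:hi])
    if not acc:
        return float("nan")
    vals = np.concatenate(acc)
    return float(np.nanmean(vals))


@dataclass(frozen=True)
class HighLowClustering:
    labels: np.ndarray  # 1 = high cluster, 0 = low cluster
    proportion_high: float
    centers: tuple[float, float]  # (low, high) on the logit scale


def cluster_high_low(
    values: Sequence[float],
    method: str = "kmeans",
    clamp: float = 1e-3,
    max_iter: int = 200,
) -> HighLowClustering:
    """Two-group clustering of methylation fractions on the logit scale.

    k-means (default) is initialized at the 10th/90th percentiles and is
    fully deterministic; a 2-component Gaussian mixture is available via
    ``method='gmm'``.  The component with the larger center is "high".
    """
    x = np.asarray(values, float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    z = logit(np.clip(x, clamp, 1 - clamp))
    if np.allclose(z, z[0]):
        warnings.warn("all values identical; single cluster", stacklevel=2)
        return HighLowClustering(np.zeros(len(x), int), 0.0, (float(z[0]), float(z[0])))

    if method == "gmm":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(
            n_components=2,
            means_init=np.percentile(z, [10, 90]).reshape(-1, 1),
            random_state=0,
        ).fit(z.reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        labels = (gm.predict(z.reshape(-1, 1)) == order[1]).astype(int)
        centers = tuple(np.sort(gm.means_.ravel()))
    elif method == "kmeans":
        lo, hi = np.percentile(z, [10, 90])
        centers_arr = np.array([lo, hi], float)
        labels = np.zeros(len(z), int)
        for _ in range(max_iter):
            labels_new = (np.abs(z - centers_arr[1]) < np.abs(z - centers_arr[0])).astype(int)
            for k in (0, 1):
                if (labels_new == k).any():
                    centers_arr[k] = z[labels_new == k].mean()
            if (labels_new == labels).all():
                labels = labels_new
                break
            labels = labels_new
        if centers_arr[1] < centers_arr[0]:
            labels = 1 - labels
            centers_arr = centers_arr[::-1]
        centers = (float(centers_arr[0]), float(centers_arr[1]))
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return HighLowClustering(labels, float(labels.mean()), centers)


@dataclass(frozen=True)
class MetageneProfile:
    """Per-bin mean methylation: 5' flank bins, scaled body bins, 3' flank bins."""

    means: np.ndarray
    counts: np.ndarray
    body_bins: int
    flank_bins: int

    @property
    def body_slice(self) -> slice:
        return slice(self.flank_bins, self.flank_bins + self.body_bins)

    @property
    def flank_means(self) -> np.ndarray:
        return np.concatenate(
            [self.means[: self.flank_bins], self.means[self.flank_bins + self.body_bins :]]
        )


def metagene(
    features: Sequence[Interval],
    sites: SiteTable,
    body_bins: int = 20,
    flank_bp: int = 1000,
    flank_bins: int = 20,
    contig_lengths: dict[str, int] | None = None,
) -> MetageneProfile:
    """Pooled metagene profile: feature bodies scaled to ``body_bins``,
    fixed-width flank bins either side; minus-strand features reversed.
    Flanks are clipped at contig ends."""
    n_bins = body_bins + 2 * flank_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    flank_width = flank_bp / flank_bins
    by_contig = sites.by_contig()
    for iv in features:
        got = by_contig.get(iv.contig)
        if got is None:
            continue
        pos, frac = got
        clen = None if contig_lengths is None else contig_lengths.get(iv.contig)
        wlo = max(0, iv.start - flank_bp)
        whi = iv.end + flank_bp if clen is None else min(clen, iv.end + flank_bp)
        lo = np.searchsorted(pos, wlo, side="left")
        hi = np.searchsorted(pos, whi, side="left")
        p = pos[lo:hi]
        f = frac[lo:hi]
        ok = ~np.isnan(f)
        p, f = p[ok], f[ok]
        if len(p) == 0:
            continue
        bins = np.empty(len(p), dtype=np.int64)
        in_body = (p >= iv.start) & (p < iv.end)
        off = p[in_body] - iv.start
        bins[in_body] = flank_bins + np.minimum(
            (body_bins * off) // iv.length, body_bins - 1
        )
        left = p < iv.start
        bins[left] = np.clip(
            ((p[left] - (iv.start - flank_bp)) // flank_width).astype(np.int64),
            0,
            flank_bins - 1,
        )
        right = p >= iv.end
        bins[right] = (
            flank_bins
            + body_bins
            + np.clip(((p[right] - iv.end) // flank_width).astype(np.int64), 0, flank_bins - 1)
        )
        if iv.strand == "-":
            bins = n_bins - 1 - bins
        np.add.at(sums, bins, f)
        np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetageneProfile(means, counts, body_bins, flank_bins)


def exon_rank_profile(
    annotation: GenomeAnnotation,
    sites: SiteTable,
    max_rank: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean methylation per exon rank (1-based from the 5' end), pooling
    ranks >= ``max_rank`` into the last slot.  Returns (means, counts)."""
    by_contig = sites.by_contig()
    sums = np.zeros(max_rank)
    counts = np.zeros(max_rank, dtype=np.int64)
    genes = {g.id: g for g in annotation.intervals("gene")}
    for gid, exons in annotation.gene_exons().items():
        if not exons:
            continue
        strand = genes[gid].strand
        ordered = exons if strand != "-" else list(reversed(exons))
        for rank0, ex in enumerate(ordered):
            slot = min(rank0, max_rank - 1)
            got = by_contig.get(ex.contig)
            if got is None:
                continue
            pos, frac = got
            lo = np.searchsorted(pos, ex.start, side="left")
            hi = np.searchsorted(pos, ex.end, side="left")
            vals = frac[lo:hi]
            vals = vals[~np.isnan(vals)]
            sums[slot] += vals.sum()
            counts[slot] += len(vals)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    t: float
    df: int
    p: float
    n_genes: int


def exon_intron_paired_test(
    exon_meths: Sequence[FeatureMethylation],
    intron_meths: Sequence[FeatureMethylation],
) -> PairedTestResult:
    """Paired t-test of per-gene (mean exon - mean intron) methylation.

    Feature means are averaged within each gene; only genes with defined
    values on both sides enter the test.
    """

    def _per_gene(fms: Sequence[FeatureMethylation]) -> dict[str, float]:
        acc: dict[str, list[float]] = {}
        for fm in fms:
            if fm.defined and fm.feature.parent is not None:
                acc.setdefault(fm.feature.parent, []).append(fm.mean_methylation)
        return {g: float(np.mean(v)) for g, v in acc.items()}

    ex = _per_gene(exon_meths)
    intr = _per_gene(intron_meths)
    shared = sorted(set(ex) & set(intr))
    if len(shared) < 2:
        raise ValueError("need at least 2 genes with both exon and intron means")
    diffs = np.array([ex[g] - intr[g] for g in shared])
    n = len(diffs)
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
    else:
        t = mean / (sd / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(float(mean), float(t), n - 1, float(p), n)
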