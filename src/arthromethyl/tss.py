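"""CAGE CTSS clustering, interquantile TSS width and nucleosome-occupancy
metagenes with resampled loess bands."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess


class CtssError(ValueError):
    pass


def read_ctss_bed(path) -> pd.DataFrame:
    """6-column BED of CTSS positions; score column carries the tag count."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise CtssError(f"{path}:{lineno}: expected 6 BED columns")
            rows.append((cols[0], int(cols[1]), cols[5], int(cols[4])))
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "count"])


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise CtssError(f"{path}:{lineno}: expected 4 bedGraph columns")
            rows.append((cols[0], int(cols[1]), int(cols[2]), float(cols[3])))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "value"])


def tpm_normalize(ctss: pd.DataFrame) -> pd.DataFrame:
    """Add a ``tpm`` column: 1e6 * count / total count."""
    total = ctss["count"].sum()
    if len(ctss) == 0 or total <= 0:
        raise CtssError("empty CTSS table")
    out = ctss.copy()
    out["tpm"] = 1e6 * out["count"] / total
    return out


@dataclass(frozen=True)
class TagCluster:
    contig: str
    strand: str
    positions: np.ndarray  # sorted member CTSS positions
    tpm: np.ndarray  # per-member normalized expression
    total_tpm: float
    q_low_pos: int
    q_high_pos: int
    width: int


def _quantile_positions(
    positions: np.ndarray, tpm: np.ndarray, q_low: float, q_high: float
) -> tuple[int, int]:
    """First positions at which the cumulative expression fraction reaches
    each quantile (step-function convention, no interpolation)."""
    cum = np.cumsum(tpm) / tpm.sum()
    lo = positions[np.searchsorted(cum, q_low, side="left")]
    hi = positions[np.searchsorted(cum, q_high, side="left")]
    return int(lo), int(hi)


def cluster_ctss(
    ctss: pd.DataFrame,
    max_gap: int = 20,
    q_low: float = 0.1,
    q_high: float = 0.9,
) -> list[TagCluster]:
    """Greedy distance clustering: consecutive same-strand CTSSs join a
    cluster iff their gap is <= ``max_gap``; clusters never span contigs or
    strands.  Interquantile width is computed per cluster."""
    if "tpm" not in ctss.columns:
        ctss = tpm_normalize(ctss)
    clusters: list[TagCluster] = []
    for (contig, strand), grp in ctss.groupby(["contig", "strand"], sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        tpm = grp["tpm"].to_numpy(float)
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for seg_pos, seg_tpm in zip(np.split(pos, breaks), np.split(tpm, breaks)):
            lo, hi = _quantile_positions(seg_pos, seg_tpm, q_low, q_high)
            clusters.append(
                TagCluster(
                    str(contig), str(strand), seg_pos, seg_tpm,
                    float(seg_tpm.sum()), lo, hi, hi - lo,
                )
            )
    return clusters


def interquantile_width(cluster: TagCluster, q_low: float = 0.1, q_high: float = 0.9) -> int:
    """Distance between the positions where cumulative expression reaches
    ``q_low`` and ``q_high``."""
    if len(cluster.positions) == 0:
        raise CtssError("empty cluster")
    lo, hi = _quantile_positions(cluster.positions, cluster.tpm, q_low, q_high)
    return hi - lo


def assign_clusters_to_genes(
    clusters: Sequence[TagCluster],
    tss_map: Mapping[str, tuple[str, int, str]],
    window: int = 500,
) -> dict[str, TagCluster]:
    """gene -> widest same-strand cluster whose dominant position falls
    within ``window`` bp of the annotated TSS."""
    out: dict[str, TagCluster] = {}
    for gene, (contig, tss, strand) in tss_map.items():
        best: TagCluster | None = None
        for cl in clusters:
            if cl.contig != contig or cl.strand != strand:
                continue
            dom = cl.positions[np.argmax(cl.tpm)]
            if abs(int(dom) - tss) <= window:
                if best is None or cl.width > best.width:
                    best = cl
        if best is not None:
            out[gene] = best
    return out


@dataclass(frozen=True)
class WidthContrast:
    median_high: float | None
    median_low: float | None
    u: float | None
    p: float | None


def width_contrast(
    gene_clusters: Mapping[str, TagCluster],
    high_genes: Sequence[str],
    low_genes: Sequence[str],
) -> WidthContrast:
    """Interquantile-width distributions of the high- vs low-methylation
    gene groups + Mann-Whitney p."""
    if not gene_clusters:
        raise CtssError("no assignable clusters")
    hi = [gene_clusters[g].width for g in high_genes if g in gene_clusters]
    lo = [gene_clusters[g].width for g in low_genes if g in gene_clusters]
    mh = float(np.median(hi)) if hi else None
    ml = float(np.median(lo)) if lo else None
    if not hi or not lo:
        warnings.warn("one methylation group has no assigned cluster", stacklevel=2)
        return WidthContrast(mh, ml, None, None)
    u, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
    return WidthContrast(mh, ml, float(u), float(p))


@dataclass(frozen=True)
class OccupancyMetagene:
    window_centers: np.ndarray  # bp relative to TSS
    mean: np.ndarray  # per-window mean over genes
    smooth: np.ndarray  # loess fit of the mean curve
    band_low: np.ndarray
    band_high: np.ndarray
    n_genes: int


def _track_index(track: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for contig, grp in track.groupby("contig", sort=True):
        grp = grp.sort_values("start", kind="mergesort")
        out[str(contig)] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["value"].to_numpy(float),
        )
    return out


def _window_means(
    idx, contig: str, tss: int, strand: str, window: int, flank: int
) -> np.ndarray | None:
    got = idx.get(contig)
    if got is None:
        return None
    starts, ends, values = got
    n_win = (2 * flank) // window
    out = np.full(n_win, np.nan)
    for w in range(n_win):
        lo = tss - flank + w * window
        hi = lo + window
        i = np.searchsorted(ends, lo, side="right")
        j = np.searchsorted(starts, hi, side="left")
        if j <= i:
            continue
        seg_lo = np.maximum(starts[i:j], lo)
        seg_hi = np.minimum(ends[i:j], hi)
        weights = (seg_hi - seg_lo).astype(float)
        if weights.sum() <= 0:
            continue
        out[w] = float(np.average(values[i:j], weights=weights))
    if strand == "-":
        out = out[::-1]
    return out


def occupancy_metagene(
    track: pd.DataFrame,
    tss_list: Mapping[str, tuple[str, int, str]],
    window: int = 200,
    flank: int = 2000,
    resamples: int = 100,
    keep: float = 0.9,
    seed: int = 0,
    loess_frac: float = 0.3,
) -> OccupancyMetagene:
    """Average occupancy in fixed windows spanning the TSS (minus-strand
    genes flipped), with a band from loess fits on repeated subsamples: each
    resample keeps ``keep`` of the genes, its per-window mean is loess
    smoothed, and the band is the pointwise min/max over resampled fits."""
    idx = _track_index(track)
    per_gene = []
    for gene, (contig, tss, strand) in sorted(tss_list.items()):
        means = _window_means(idx, contig, tss, strand, window, flank)
        if means is not None and not np.all(np.isnan(means)):
            per_gene.append(means)
    if not per_gene:
        raise CtssError("no genes with track coverage")
    mat = np.vstack(per_gene)
    n_win = mat.shape[1]
    centers = -flank + window / 2 + window * np.arange(n_win)
    mean = np.nanmean(mat, axis=0)
    xs = np.arange(n_win, dtype=float)

    def _loess(y: np.ndarray) -> np.ndarray:
        ok = ~np.isnan(y)
        fit = lowess(y[ok], xs[ok], frac=loess_frac, return_sorted=False)
        out = np.full(n_win, np.nan)
        out[ok] = fit
        return out

    smooth = _loess(mean)
    rng = np.random.default_rng(seed)
    k = max(1, int(round(keep * mat.shape[0])))
    lo = np.full(n_win, np.inf)
    hi = np.full(n_win, -np.inf)
    for _ in range(resamples):
        sel = rng.choice(mat.shape[0], size=k, replace=False)
        fit = _loess(np.nanmean(mat[sel], axis=0))
        lo = np.fmin(lo, fit)
        hi = np.fmax(hi, fit)
    return OccupancyMetagene(centers, mean, smooth, lo, hi, mat.shape[0])
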