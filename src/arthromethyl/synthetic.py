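"""Synthetic data generation: annotated genomes, true methylomes, bisulfite
counts, BM tip traits, tissue-structured expression, CTSS tags and
nucleosome-occupancy tracks.

Architectural presets mirror the methylome classes the analyses expect:

``strigamia-like``
    TE- and exon-enriched methylation, nucleosome-phased exonic (and TE)
    sites, promoter silencing of a gene subset, expression/TSS coupling.
``holometabolan``
    Exon-restricted methylation of a gene subset; TEs and background near
    zero; no promoter silencing.
``crustacean-null``
    Uniform low methylation, no periodic signal, no coupling between
    methylation and expression -- a null for calibration tests.

All generators are deterministic given the config seed; independent
substreams are derived per stage so adding a stage never perturbs another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, Interval, derive_upstream, write_gff3
from .phylo import PhyloTree, TreeError
from .sites import SiteTable, write_cytosine_report

SPIKE_CONTIG = "spike"

_STAGE = {
    "genome": 0,
    "methylome": 1,
    "counts": 2,
    "tree": 3,
    "expression": 4,
    "ctss": 5,
    "occupancy": 6,
}


class PackingError(ValueError):
    """Requested features exceed contig capacity."""


class ConfigError(ValueError):
    pass


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGE[stage]])


@dataclass
class SimConfig:
    seed: int = 0
    n_contigs: int = 10
    contig_length: int = 50_000
    n_genes: int = 100
    exon_count_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.15, 0.1, 0.05, 0.05, 0.05)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (60, 200)
    n_tes: int = 50
    te_length_range: tuple[int, int] = (300, 1000)
    cpg_density: float = 0.02
    architecture: str = "strigamia-like"
    nucleosome_repeat_length: int = 160
    periodic_amplitude: float = 0.2
    class_means: dict[str, float] = field(
        default_factory=lambda: dict(_PRESETS["strigamia-like"]["class_means"])
    )
    methylated_gene_fraction: float = 0.35
    silenced_gene_fraction: float = 0.10
    te_phased: bool = True
    coverage_mean: float = 30.0
    nonconversion_rate: float = 0.005
    failed_methylated_conversion: float = 0.0
    spike_in_sites: int = 200
    n_tissues: int = 4
    housekeeping_cv: float = 0.1
    tissuespecific_cv: float = 1.0
    expression_coupling: bool = True
    silencing_factor: float = 0.02
    broad_tss_span: int = 40
    narrow_tss_span: int = 1
    ctss_tags_per_gene: int = 200
    occupancy_amplitude: float = 0.5
    occupancy_noise_sd: float = 0.05
    occupancy_bin: int = 20
    upstream_length: int = 1000

    def validate(self) -> None:
        for name in ("cpg_density", "nonconversion_rate", "failed_methylated_conversion",
                     "methylated_gene_fraction", "silenced_gene_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.periodic_amplitude <= 0.5:
            raise ConfigError("periodic_amplitude must be in [0, 0.5]")
        for cls, mean in self.class_means.items():
            if not 0 <= mean <= 1:
                raise ConfigError(f"class mean {cls}={mean} outside [0, 1]")
        phased = ["exon"] + (["te"] if self.te_phased else [])
        for cls in phased:
            if self.class_means.get(cls, 0) + self.periodic_amplitude > 1:
                raise ConfigError(f"class mean {cls} + amplitude exceeds 1")
        if abs(sum(self.exon_count_probs) - 1) > 1e-9:
            raise ConfigError("exon_count_probs must sum to 1")
        if self.nonconversion_rate >= 1:
            raise ConfigError("nonconversion_rate must be < 1")

    @classmethod
    def preset(cls, name: str, seed: int = 0, **overrides) -> "SimConfig":
        key = _PRESET_ALIASES.get(name, name)
        if key not in _PRESETS:
            raise ConfigError(f"unknown architecture preset {name!r}")
        params = dict(_PRESETS[key])
        params["class_means"] = dict(params["class_means"])
        params.update(overrides)
        cfg = cls(seed=seed, architecture=key, **params)
        cfg.validate()
        return cfg


_PRESETS: dict[str, dict] = {
    "strigamia-like": dict(
        class_means=dict(
            exon=0.65, intron=0.25, te=0.55, background=0.10,
            upstream=0.05, upstream_silenced=0.75, gene_off=0.02,
        ),
        te_phased=True,
        periodic_amplitude=0.2,
        methylated_gene_fraction=0.35,
        silenced_gene_fraction=0.10,
        expression_coupling=True,
    ),
    "holometabolan": dict(
        class_means=dict(
            exon=0.70, intron=0.05, te=0.02, background=0.03,
            upstream=0.02, upstream_silenced=0.02, gene_off=0.01,
        ),
        te_phased=False,
        periodic_amplitude=0.2,
        methylated_gene_fraction=0.30,
        silenced_gene_fraction=0.0,
        expression_coupling=True,
    ),
    "crustacean-null": dict(
        class_means=dict(
            exon=0.15, intron=0.15, te=0.15, background=0.15,
            upstream=0.15, upstream_silenced=0.15, gene_off=0.15,
        ),
        te_phased=False,
        periodic_amplitude=0.0,
        methylated_gene_fraction=0.35,
        silenced_gene_fraction=0.0,
        expression_coupling=False,
    ),
}
_PRESET_ALIASES = {"holometalan": "holometabolan"}


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[GenomeAnnotation, dict[str, np.ndarray]]:
    """Place non-overlapping genes (with exon/intron structure) and TEs on
    contigs and scatter CpG dyads at the configured density (>=2 bp apart).
    """
    config.validate()
    rng = _stage_rng(config.seed, "genome")
    n_exon_choices = len(config.exon_count_probs)

    specs: list[tuple[str, int, list[int]]] = []  # (kind, idx, part lengths)
    for i in range(config.n_genes):
        k = int(rng.choice(np.arange(1, n_exon_choices + 1), p=config.exon_count_probs))
        parts: list[int] = []
        for j in range(k):
            parts.append(int(rng.integers(*config.exon_length_range, endpoint=True)))
            if j < k - 1:
                parts.append(int(rng.integers(*config.intron_length_range, endpoint=True)))
        specs.append(("gene", i, parts))
    for i in range(config.n_tes):
        specs.append(("TE", i, [int(rng.integers(*config.te_length_range, endpoint=True))]))

    order = rng.permutation(len(specs))
    contigs = [f"contig{c:03d}" for c in range(config.n_contigs)]
    per_contig: dict[str, list[tuple[str, int, list[int]]]] = {c: [] for c in contigs}
    for slot, oi in enumerate(order):
        per_contig[contigs[slot % config.n_contigs]].append(specs[oi])

    ann = GenomeAnnotation({c: config.contig_length for c in contigs})
    for contig in contigs:
        feats = per_contig[contig]
        total = sum(sum(parts) for _, _, parts in feats)
        if total > config.contig_length:
            raise PackingError(
                f"{contig}: features need {total} bp > contig length {config.contig_length}"
            )
        leftover = config.contig_length - total
        cuts = np.sort(rng.integers(0, leftover + 1, size=len(feats)))
        cursor = 0
        prev_cut = 0
        for (kind, idx, parts), cut in zip(feats, cuts):
            cursor += int(cut) - prev_cut
            prev_cut = int(cut)
            start = cursor
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "gene":
                gid = f"g{idx:05d}"
                span = sum(parts)
                ann.add(Interval(contig, start, start + span, strand, "gene", id=gid))
                off = start
                for j, plen in enumerate(parts):
                    if j % 2 == 0:
                        ann.add(
                            Interval(contig, off, off + plen, strand, "exon",
                                     parent=gid, id=f"{gid}.e{j // 2 + 1}")
                        )
                    off += plen
                cursor += span
            else:
                ann.add(
                    Interval(contig, start, start + parts[0], strand, "TE", id=f"te{idx:05d}")
                )
                cursor += parts[0]

    cpgs: dict[str, np.ndarray] = {}
    for contig in contigs:
        candidates = np.arange(0, config.contig_length - 1, 2)
        n_sites = min(len(candidates), int(round(config.cpg_density * config.contig_length)))
        cpgs[contig] = np.sort(rng.choice(candidates, size=n_sites, replace=False))
    return ann, cpgs


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

@dataclass
class TrueMethylome:
    """Latent per-dyad methylation probabilities plus generation truth."""

    frame: pd.DataFrame  # contig, pos, p, fclass, gene
    gene_classes: pd.DataFrame  # gene, methylated, silenced
    phases: dict[str, float]
    config: SimConfig

    def by_contig(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for contig, grp in self.frame.groupby("contig", sort=True):
            out[str(contig)] = (grp["pos"].to_numpy(), grp["p"].to_numpy())
        return out

    def class_mean(self, fclass: str) -> float:
        sel = self.frame[self.frame["fclass"] == fclass]
        return float(sel["p"].mean())


def _site_classes(
    annotation: GenomeAnnotation, positions: np.ndarray, contig: str, upstream: list[Interval]
) -> tuple[np.ndarray, np.ndarray]:
    """Class label and owning gene id per site (priority exon > intron > TE >
    upstream > background)."""
    cls = np.full(len(positions), "background", dtype=object)
    gene = np.full(len(positions), "", dtype=object)
    layers = [
        ("upstream", upstream),
        ("te", annotation.intervals("TE", contig=contig)),
        ("intron", annotation.intervals("intron", contig=contig)),
        ("exon", annotation.intervals("exon", contig=contig)),
    ]
    for label, ivs in layers:
        for iv in ivs:
            lo = np.searchsorted(positions, iv.start, side="left")
            hi = np.searchsorted(positions, iv.end, side="left")
            if hi > lo:
                cls[lo:hi] = label
                gene[lo:hi] = iv.parent or (iv.id or "")
    return cls, gene


def simulate_methylome(
    annotation: GenomeAnnotation,
    cpgs: dict[str, np.ndarray],
    config: SimConfig,
) -> TrueMethylome:
    """True per-site probabilities: class means plus, inside exons (and TEs
    when the preset is phased), a cosine of the nucleosome repeat length with
    a random phase per contig.  A configured fraction of genes forms the
    methylated class; the rest sit near zero, giving a bimodal gene-level
    distribution.  Intron and background sites carry no periodic term.
    """
    config.validate()
    cm = config.class_means
    for needed in ("exon", "intron", "te", "background", "upstream", "upstream_silenced", "gene_off"):
        if needed not in cm:
            raise ConfigError(f"class_means missing {needed!r}")
    rng = _stage_rng(config.seed, "methylome")
    genes = sorted(g.id for g in annotation.intervals("gene"))
    methylated = {g: bool(rng.random() < config.methylated_gene_fraction) for g in genes}
    unmeth = [g for g in genes if not methylated[g]]
    n_sil = int(round(config.silenced_gene_fraction * len(genes)))
    silenced_list = list(rng.choice(unmeth, size=min(n_sil, len(unmeth)), replace=False))
    silenced = {g: g in set(silenced_list) for g in genes}

    with_upstream = derive_upstream(annotation, config.upstream_length)
    ups_by_contig: dict[str, list[Interval]] = {}
    for iv in with_upstream.intervals("upstream"):
        ups_by_contig.setdefault(iv.contig, []).append(iv)

    L = config.nucleosome_repeat_length
    A = config.periodic_amplitude
    rows = []
    phases: dict[str, float] = {}
    for contig in sorted(cpgs):
        positions = cpgs[contig]
        phi = float(rng.uniform(0, L))
        phases[contig] = phi
        cls, gene = _site_classes(annotation, positions, contig, ups_by_contig.get(contig, []))
        p = np.full(len(positions), cm["background"])
        cosine = np.cos(2 * np.pi * (positions - phi) / L)
        for label in ("exon", "intron"):
            sel = cls == label
            if not sel.any():
                continue
            is_meth = np.array([methylated.get(g, False) for g in gene[sel]])
            vals = np.where(is_meth, cm[label], cm["gene_off"])
            if label == "exon" and A > 0:
                vals = vals + np.where(is_meth, A * cosine[sel], 0.0)
            p[sel] = vals
        sel = cls == "te"
        if sel.any():
            vals = np.full(sel.sum(), cm["te"])
            if config.te_phased and A > 0:
                vals = vals + A * cosine[sel]
            p[sel] = vals
        sel = cls == "upstream"
        if sel.any():
            is_sil = np.array([silenced.get(g, False) for g in gene[sel]])
            p[sel] = np.where(is_sil, cm["upstream_silenced"], cm["upstream"])
        p = np.clip(p, 0.0, 1.0)
        rows.append(
            pd.DataFrame(
                {"contig": contig, "pos": positions, "p": p, "fclass": cls, "gene": gene}
            )
        )
    frame = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["contig", "pos", "p", "fclass", "gene"]
    )
    gene_classes = pd.DataFrame(
        {
            "gene": genes,
            "methylated": [methylated[g] for g in genes],
            "silenced": [silenced[g] for g in genes],
        }
    )
    return TrueMethylome(frame, gene_classes, phases, config)


# ---------------------------------------------------------------------------
# Bisulfite counts
# ---------------------------------------------------------------------------

def _draw_counts(
    p: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    q = p * (1 - config.failed_methylated_conversion) + (1 - p) * config.nonconversion_rate
    tot_p = rng.poisson(config.coverage_mean, size=len(p))
    tot_m = rng.poisson(config.coverage_mean, size=len(p))
    meth_p = rng.binomial(tot_p, q)
    meth_m = rng.binomial(tot_m, q)
    return meth_p, tot_p, meth_m, tot_m


def simulate_bisulfite_counts(
    methylome: TrueMethylome, config: SimConfig | None = None
) -> tuple[SiteTable, SiteTable]:
    """Observed read counts: per strand, totals ~ Poisson(coverage_mean) and
    methylated reads ~ Binomial(total, q) with q folding in non-conversion
    error.  Returns (sample table, unmethylated spike-in table on the
    reserved contig ``spike``)."""
    config = config or methylome.config
    config.validate()
    rng = _stage_rng(config.seed, "counts")
    p = methylome.frame["p"].to_numpy(float)
    meth_p, tot_p, meth_m, tot_m = _draw_counts(p, config, rng)
    sample = SiteTable(
        pd.DataFrame(
            {
                "contig": methylome.frame["contig"],
                "pos": methylome.frame["pos"],
                "meth_plus": meth_p,
                "total_plus": tot_p,
                "meth_minus": meth_m,
                "total_minus": tot_m,
            }
        )
    )
    sp = np.zeros(config.spike_in_sites)
    smeth_p, stot_p, smeth_m, stot_m = _draw_counts(sp, config, rng)
    spike = SiteTable(
        pd.DataFrame(
            {
                "contig": SPIKE_CONTIG,
                "pos": np.arange(config.spike_in_sites) * 2,
                "meth_plus": smeth_p,
                "total_plus": stot_p,
                "meth_minus": smeth_m,
                "total_minus": stot_m,
            }
        )
    )
    return sample, spike


# ---------------------------------------------------------------------------
# Brownian-motion tip traits
# ---------------------------------------------------------------------------

def simulate_tree_tips(
    tree: PhyloTree, root_value: float, sigma2: float, seed: int = 0
) -> tuple[dict[str, float], dict[str, float]]:
    """Evolve a trait by Brownian motion from the root: each child is
    parent + Normal(0, sigma2 * branch length).  Returns (tip values,
    all-node truth including internal nodes)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng([seed, _STAGE["tree"]])
    values: dict[int, float] = {}
    truth: dict[str, float] = {}
    tips: dict[str, float] = {}
    for node in tree.nodes:  # preorder
        if node.parent is None:
            values[node.index] = float(root_value)
        else:
            bl = node.edge_length
            if bl is None or bl < 0:
                raise TreeError(f"negative branch length above {node.label!r}")
            step = rng.normal(0.0, np.sqrt(sigma2 * bl)) if sigma2 > 0 else 0.0
            values[node.index] = values[node.parent] + step
        truth[node.label] = values[node.index]
        if node.is_tip:
            tips[node.label] = values[node.index]
    return tips, truth


# ---------------------------------------------------------------------------
# Expression, CTSS, occupancy
# ---------------------------------------------------------------------------

def _housekeeping_set(truth: TrueMethylome, config: SimConfig, rng: np.random.Generator) -> set[str]:
    gc = truth.gene_classes
    if config.expression_coupling:
        return set(gc.loc[gc["methylated"], "gene"])
    n = int(gc["methylated"].sum())
    return set(rng.choice(gc["gene"].to_numpy(), size=n, replace=False))


def simulate_expression(
    truth: TrueMethylome, config: SimConfig | None = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Log-normal gene x tissue abundances.  Housekeeping-like genes (the
    methylated class when coupling is on) get low cross-tissue CV and a high
    expression floor; others are tissue-variable.  Promoter-silenced genes
    are scaled down by the silencing factor.  Returns (table, sample->tissue).
    """
    config = config or truth.config
    rng = _stage_rng(config.seed, "expression")
    gc = truth.gene_classes
    genes = list(gc["gene"])
    hk = _housekeeping_set(truth, config, rng)
    silenced = set(gc.loc[gc["silenced"], "gene"])
    is_hk = np.array([g in hk for g in genes])
    base = np.where(
        is_hk,
        np.exp(rng.normal(2.5, 0.5, size=len(genes))),
        np.exp(rng.normal(1.0, 1.5, size=len(genes))),
    )
    base = np.where([g in silenced for g in genes], base * config.silencing_factor, base)
    cv = np.where(is_hk, config.housekeeping_cv, config.tissuespecific_cv)
    sigma = np.sqrt(np.log1p(cv ** 2))
    cols = {}
    for t in range(config.n_tissues):
        noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma))
        cols[f"tissue{t}"] = base * noise
    table = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return table, {c: c for c in table.columns}


def gene_tss(annotation: GenomeAnnotation) -> dict[str, tuple[str, int, str]]:
    """gene id -> (contig, 0-based TSS position, strand)."""
    out = {}
    for g in annotation.intervals("gene"):
        pos = g.start if g.strand != "-" else g.end - 1
        out[g.id] = (g.contig, pos, g.strand)
    return out


def simulate_ctss(
    annotation: GenomeAnnotation, truth: TrueMethylome, config: SimConfig | None = None
) -> pd.DataFrame:
    """CAGE tag counts per (contig, pos, strand).  Broad-class genes spread
    tags over ``broad_tss_span`` bp downstream of the TSS; narrow-class genes
    concentrate them on ``narrow_tss_span`` positions."""
    config = config or truth.config
    rng = _stage_rng(config.seed, "ctss")
    hk = _housekeeping_set(truth, config, rng)
    tss = gene_tss(annotation)
    recs: dict[tuple[str, int, str], int] = {}
    for gene in truth.gene_classes["gene"]:
        contig, pos, strand = tss[gene]
        span = config.broad_tss_span if gene in hk else config.narrow_tss_span
        total = max(1, int(rng.poisson(config.ctss_tags_per_gene)))
        counts = rng.multinomial(total, np.full(span, 1.0 / span))
        step = 1 if strand != "-" else -1
        for off, cnt in enumerate(counts):
            if cnt == 0:
                continue
            at = pos + step * off
            clen = annotation.contig_lengths[contig]
            at = min(max(at, 0), clen - 1)
            key = (contig, at, strand)
            recs[key] = recs.get(key, 0) + int(cnt)
    rows = [(c, p, s, n) for (c, p, s), n in sorted(recs.items())]
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "count"])


def simulate_occupancy(
    annotation: GenomeAnnotation, truth: TrueMethylome, config: SimConfig | None = None
) -> pd.DataFrame:
    """Binned occupancy track: flat noise everywhere, plus a raised cosine of
    period ``nucleosome_repeat_length`` over 2 kb downstream of broad-class
    TSSs.  Returns bedGraph-style (contig, start, end, value) rows."""
    config = config or truth.config
    rng = _stage_rng(config.seed, "occupancy")
    hk = _housekeeping_set(truth, config, rng)
    tss = gene_tss(annotation)
    L = config.nucleosome_repeat_length
    binw = config.occupancy_bin
    rows = []
    for contig in sorted(annotation.contig_lengths):
        clen = annotation.contig_lengths[contig]
        n_bins = clen // binw
        vals = 1.0 + rng.normal(0.0, config.occupancy_noise_sd, size=n_bins)
        centers = np.arange(n_bins) * binw + binw / 2
        for gene in truth.gene_classes["gene"]:
            gcontig, pos, strand = tss[gene]
            if gcontig != contig or gene not in hk:
                continue
            if strand != "-":
                d = centers - pos
            else:
                d = pos - centers
            sel = (d >= 0) & (d < 2000)
            vals[sel] += config.occupancy_amplitude * (1 + np.cos(2 * np.pi * d[sel] / L)) / 2
        starts = np.arange(n_bins) * binw
        rows.append(
            pd.DataFrame(
                {"contig": contig, "start": starts, "end": starts + binw, "value": vals}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Writers / one-shot driver
# ---------------------------------------------------------------------------

def write_expression_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")


def write_ctss_bed(ctss: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in ctss.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.pos}\t{row.pos + 1}\tctss\t{row.count}\t{row.strand}\n")


def write_bedgraph(track: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


#: Fixed 8-tip demo tree (time-scaled, ultrametric) used by the pipeline.
DEMO_TREE = (
    "(((A:50,B:50):100,(C:80,D:80):70):150,((E:60,F:60):120,(G:90,H:90):90):120);"
)


@dataclass(frozen=True)
class SimResult:
    annotation: GenomeAnnotation
    cpgs: dict[str, np.ndarray]
    methylome: TrueMethylome
    sample: SiteTable
    spike: SiteTable
    expression: pd.DataFrame
    tissues: dict[str, str]
    ctss: pd.DataFrame
    occupancy: pd.DataFrame
    tree: PhyloTree
    tip_values: dict[str, float]
    node_truth: dict[str, float]


def simulate_all(config: SimConfig) -> SimResult:
    """Run every generator off one config (each stage on its own substream)."""
    annotation, cpgs = simulate_genome(config)
    methylome = simulate_methylome(annotation, cpgs, config)
    sample, spike = simulate_bisulfite_counts(methylome, config)
    expression, tissues = simulate_expression(methylome, config)
    ctss = simulate_ctss(annotation, methylome, config)
    occupancy = simulate_occupancy(annotation, methylome, config)
    tree = PhyloTree.from_newick(DEMO_TREE)
    tips, node_truth = simulate_tree_tips(tree, root_value=10.0, sigma2=0.05, seed=config.seed)
    return SimResult(
        annotation, cpgs, methylome, sample, spike, expression, tissues,
        ctss, occupancy, tree, tips, node_truth,
    )


def write_all(result: SimResult, outdir) -> dict[str, str]:
    """Write every simulated artifact as plain text; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_gff3": out / "genome.gff3",
        "cytosine_report": out / "cytosine_report.tsv",
        "spike_report": out / "spike_report.tsv",
        "methylome_truth": out / "methylome_truth.tsv",
        "gene_classes": out / "gene_classes.tsv",
        "expression": out / "expression.tsv",
        "ctss": out / "ctss.bed",
        "occupancy": out / "occupancy.bedgraph",
        "tree": out / "tree.nwk",
        "tip_values": out / "tip_values.tsv",
        "node_truth": out / "node_truth.tsv",
    }
    write_gff3(result.annotation, paths["genome_gff3"])
    write_cytosine_report(result.sample, paths["cytosine_report"])
    write_cytosine_report(result.spike, paths["spike_report"])
    result.methylome.frame.to_csv(paths["methylome_truth"], sep="\t", index=False, float_format="%.6g")
    result.methylome.gene_classes.to_csv(paths["gene_classes"], sep="\t", index=False)
    write_expression_tsv(result.expression, paths["expression"])
    write_ctss_bed(result.ctss, paths["ctss"])
    write_bedgraph(result.occupancy, paths["occupancy"])
    with open(paths["tree"], "w") as fh:
        fh.write(result.tree.to_newick() + "\n")
    pd.Series(result.tip_values, name="trait").rename_axis("species").to_csv(
        paths["tip_values"], sep="\t", float_format="%.10g"
    )
    pd.Series(result.node_truth, name="trait").rename_axis("node").to_csv(
        paths["node_truth"], sep="\t", float_format="%.10g"
    )
    return {k: str(v) for k, v in paths.items()}


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["exon_count_probs"] = list(d["exon_count_probs"])
    return d
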