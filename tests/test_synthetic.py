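import numpy as np
import pandas as pd
import pytest

from arthromethyl.annotation import write_gff3
from arthromethyl.phylo import PhyloTree
from arthromethyl.synthetic import (
    ConfigError,
    PackingError,
    SimConfig,
    simulate_all,
    simulate_bisulfite_counts,
    simulate_ctss,
    simulate_expression,
    simulate_genome,
    simulate_methylome,
    simulate_occupancy,
    simulate_tree_tips,
    write_all,
)


def small_config(preset="strigamia-like", **kw):
    defaults = dict(
        seed=0, n_contigs=4, contig_length=20_000, n_genes=20, n_tes=10,
        cpg_density=0.02,
    )
    defaults.update(kw)
    return SimConfig.preset(preset, **defaults)


# -- genome -----------------------------------------------------------------

def test_single_exon_gene_has_no_introns():
    cfg = SimConfig.preset(
        "strigamia-like", seed=1, n_contigs=1, contig_length=10_000, n_genes=1,
        n_tes=0, exon_count_probs=(1.0,) + (0.0,) * 7,
    )
    ann, _ = simulate_genome(cfg)
    assert len(ann.intervals("gene")) == 1
    assert len(ann.intervals("exon")) == 1
    assert len(ann.intervals("intron")) == 0


def test_empty_genome():
    cfg = SimConfig.preset("strigamia-like", seed=0, n_contigs=2,
                           contig_length=5000, n_genes=0, n_tes=0)
    ann, cpgs = simulate_genome(cfg)
    assert len(ann.intervals("gene")) == 0
    assert len(ann.intervals("TE")) == 0
    assert all(len(v) > 0 for v in cpgs.values())


def test_genome_deterministic_gff3_bytes(tmp_path):
    cfg = small_config(seed=9)
    for run in ("a", "b"):
        ann, _ = simulate_genome(cfg)
        write_gff3(ann, tmp_path / f"{run}.gff3")
    assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()


def test_features_do_not_overlap():
    cfg = small_config(seed=4)
    ann, _ = simulate_genome(cfg)
    top = sorted(ann.intervals("gene") + ann.intervals("TE"))
    for a, b in zip(top, top[1:]):
        if a.contig == b.contig:
            assert a.end <= b.start


def test_infeasible_packing_errors():
    cfg = SimConfig.preset(
        "strigamia-like", seed=0, n_contigs=1, contig_length=3000, n_genes=30, n_tes=0,
    )
    with pytest.raises(PackingError):
        simulate_genome(cfg)


def test_cpg_min_spacing():
    cfg = small_config(seed=2, cpg_density=0.2)
    _, cpgs = simulate_genome(cfg)
    for pos in cpgs.values():
        assert np.diff(pos).min() >= 2


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        SimConfig.preset("strigamia-like", periodic_amplitude=0.9)
    with pytest.raises(ConfigError):
        SimConfig.preset("no-such-preset")


# -- methylome --------------------------------------------------------------

def test_zero_amplitude_exons_flat():
    cfg = SimConfig.preset(
        "strigamia-like", seed=3, n_contigs=2, contig_length=20_000, n_genes=10,
        n_tes=0, periodic_amplitude=0.0, methylated_gene_fraction=1.0,
    )
    cfg.class_means["exon"] = 0.8
    ann, cpgs = simulate_genome(cfg)
    meth = simulate_methylome(ann, cpgs, cfg)
    exonic = meth.frame[meth.frame["fclass"] == "exon"]
    assert len(exonic) > 0
    assert (exonic["p"] == 0.8).all()


def test_periodic_probabilities_within_band_and_autocorrelation_peak():
    L = 160
    cfg = SimConfig.preset(
        "strigamia-like", seed=5, n_contigs=1, contig_length=60_000, n_genes=10,
        n_tes=0, cpg_density=0.25, nucleosome_repeat_length=L,
        periodic_amplitude=0.2, methylated_gene_fraction=1.0,
        exon_count_probs=(1.0,) + (0.0,) * 7, exon_length_range=(3000, 4000),
    )
    cfg.class_means["exon"] = 0.5
    ann, cpgs = simulate_genome(cfg)
    meth = simulate_methylome(ann, cpgs, cfg)
    ex = meth.frame[meth.frame["fclass"] == "exon"]
    assert ex["p"].min() >= 0.3 - 1e-9
    assert ex["p"].max() <= 0.7 + 1e-9
    # autocorrelation oracle on the dense per-bp reconstruction of one exon
    exon = ann.intervals("exon")[0]
    sel = ex[(ex["pos"] >= exon.start) & (ex["pos"] < exon.end)]
    pos = sel["pos"].to_numpy()
    p = sel["p"].to_numpy() - sel["p"].mean()
    grid = np.zeros(exon.length)
    mask = np.zeros(exon.length, bool)
    grid[pos - exon.start] = p
    mask[pos - exon.start] = True
    lags = np.arange(120, 201)
    ac = np.array([
        np.sum(grid[:-lag] * grid[lag:]) / max(1, np.sum(mask[:-lag] & mask[lag:]))
        for lag in lags
    ])
    assert abs(int(lags[np.argmax(ac)]) - L) <= 10


def test_holometabolan_te_below_background():
    cfg = SimConfig.preset(
        "holometabolan", seed=7, n_contigs=5, contig_length=40_000,
        n_genes=30, n_tes=40,
    )
    ann, cpgs = simulate_genome(cfg)
    meth = simulate_methylome(ann, cpgs, cfg)
    assert meth.class_mean("te") < meth.class_mean("background") + 0.01


def test_strigamia_architecture_fidelity():
    """Realized TE mean exceeds background by >= half the configured gap."""
    cfg = SimConfig.preset(
        "strigamia-like", seed=11, n_contigs=25, contig_length=60_000,
        n_genes=50, n_tes=520, te_length_range=(300, 600), cpg_density=0.03,
    )
    ann, cpgs = simulate_genome(cfg)
    assert len(ann.intervals("TE")) >= 500
    meth = simulate_methylome(ann, cpgs, cfg)
    gap = cfg.class_means["te"] - cfg.class_means["background"]
    assert meth.class_mean("te") > meth.class_mean("background") + gap / 2


def test_methylome_bimodal_gene_assignment():
    cfg = small_config(seed=13)
    ann, cpgs = simulate_genome(cfg)
    meth = simulate_methylome(ann, cpgs, cfg)
    gc = meth.gene_classes
    assert set(gc.columns) == {"gene", "methylated", "silenced"}
    assert 0 < gc["methylated"].sum() < len(gc)


# -- bisulfite counts -------------------------------------------------------

def _tiny_methylome(p_value, n=500, cfg=None):
    cfg = cfg or small_config()
    frame = pd.DataFrame(
        {
            "contig": "c0",
            "pos": np.arange(n) * 2,
            "p": p_value,
            "fclass": "background",
            "gene": "",
        }
    )
    from arthromethyl.synthetic import TrueMethylome

    return TrueMethylome(frame, pd.DataFrame(columns=["gene", "methylated", "silenced"]), {}, cfg)


def test_counts_fully_methylated_perfect_conversion():
    cfg = small_config(seed=1, nonconversion_rate=0.0)
    meth = _tiny_methylome(1.0, cfg=cfg)
    sample, _ = simulate_bisulfite_counts(meth, cfg)
    df = sample.frame
    assert (df["meth_plus"] == df["total_plus"]).all()
    assert (df["meth_minus"] == df["total_minus"]).all()


def test_spike_in_rate_within_binomial_se():
    cfg = small_config(seed=2, nonconversion_rate=0.005, spike_in_sites=2000,
                       coverage_mean=30)
    meth = _tiny_methylome(0.5, n=10, cfg=cfg)
    _, spike = simulate_bisulfite_counts(meth, cfg)
    df = spike.frame
    k = (df["meth_plus"] + df["meth_minus"]).sum()
    n = (df["total_plus"] + df["total_minus"]).sum()
    assert n > 1e5 * 0.9
    se = np.sqrt(0.005 * 0.995 / n)
    assert abs(k / n - 0.005) < 3 * se


def test_observed_fraction_clt_bound():
    cfg = small_config(seed=3, coverage_mean=30, nonconversion_rate=0.0)
    meth = _tiny_methylome(0.5, n=1000, cfg=cfg)
    sample, _ = simulate_bisulfite_counts(meth, cfg)
    frac = sample.fractions()
    se = np.sqrt(0.5 * 0.5 / (2 * 30 * 1000))
    assert abs(np.nanmean(frac) - 0.5) < 3 * se


def test_count_conservation_everywhere():
    cfg = small_config(seed=5)
    ann, cpgs = simulate_genome(cfg)
    meth = simulate_methylome(ann, cpgs, cfg)
    sample, spike = simulate_bisulfite_counts(meth, cfg)
    for t in (sample, spike):
        df = t.frame
        assert (df["meth_plus"] <= df["total_plus"]).all()
        assert (df["meth_minus"] <= df["total_minus"]).all()


# -- expression / ctss / occupancy ------------------------------------------

def test_cv_parameter_ordering():
    cfg_lo = small_config(seed=6, housekeeping_cv=0.1, tissuespecific_cv=1.0)
    ann, cpgs = simulate_genome(cfg_lo)
    meth = simulate_methylome(ann, cpgs, cfg_lo)
    expr, _ = simulate_expression(meth, cfg_lo)
    gc = meth.gene_classes.set_index("gene")
    cv = expr.std(axis=1, ddof=1) / expr.mean(axis=1)
    hk = gc["methylated"]
    assert cv[hk].median() < cv[~hk].median()


def test_narrow_span_one_position_per_gene():
    cfg = small_config(seed=7, narrow_tss_span=1, expression_coupling=True)
    ann, cpgs = simulate_genome(cfg)
    meth = simulate_methylome(ann, cpgs, cfg)
    ctss = simulate_ctss(ann, meth, cfg)
    gc = meth.gene_classes.set_index("gene")
    from arthromethyl.synthetic import gene_tss

    tss = gene_tss(ann)
    narrow = [g for g in gc.index if not gc.loc[g, "methylated"]]
    for g in narrow:
        contig, pos, strand = tss[g]
        sub = ctss[(ctss["contig"] == contig) & (ctss["strand"] == strand)]
        assert pos in set(sub["pos"])


def test_occupancy_zero_amplitude_flat():
    cfg = small_config(seed=8, occupancy_amplitude=0.0, occupancy_noise_sd=0.0)
    ann, cpgs = simulate_genome(cfg)
    meth = simulate_methylome(ann, cpgs, cfg)
    occ = simulate_occupancy(ann, meth, cfg)
    assert occ["value"].nunique() == 1


# -- tree tips --------------------------------------------------------------

def test_tree_tip_truth_contains_internal_nodes():
    t = PhyloTree.from_newick("((A:1,B:1)n1:1,C:2)root;")
    tips, truth = simulate_tree_tips(t, 1.0, 0.5, seed=3)
    assert set(tips) == {"A", "B", "C"}
    assert len(truth) == 5


def test_negative_sigma2_rejected():
    t = PhyloTree.from_newick("(A:1,B:1);")
    with pytest.raises(ValueError):
        simulate_tree_tips(t, 0.0, -1.0)


# -- determinism across all generators --------------------------------------

def test_full_determinism(tmp_path):
    cfg = small_config(seed=21)
    hashes = []
    for run in ("x", "y"):
        res = simulate_all(cfg)
        paths = write_all(res, tmp_path / run)
        hashes.append({k: open(v, "rb").read() for k, v in paths.items()})
    assert hashes[0].keys() == hashes[1].keys()
    for k in hashes[0]:
        assert hashes[0][k] == hashes[1][k], k


def test_seed_changes_output():
    a = simulate_all(small_config(seed=1))
    b = simulate_all(small_config(seed=2))
    assert not a.sample.frame.equals(b.sample.frame)
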