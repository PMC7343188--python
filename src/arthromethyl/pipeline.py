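"""End-to-end orchestration: simulate -> annotate -> summarize ->
periodicity -> phylo -> expression -> tss from one validated config, with a
manifest of seeds, parameters and output checksums."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import expression as expr_mod
from . import features as feat_mod
from . import periodicity as per_mod
from . import phylo as phylo_mod
from . import sites as sites_mod
from . import synthetic as syn_mod
from . import tss as tss_mod


class ConfigError(ValueError):
    pass


_DEFAULTS = {
    "seed": 0,
    "simulate": {"preset": "strigamia-like", "overrides": {}},
    "stages": {
        "annotation": True,
        "sites": True,
        "features": True,
        "periodicity": True,
        "phylo": True,
        "expression": True,
        "tss": True,
    },
    "params": {
        "min_coverage": 10,
        "min_cpgs": 3,
        "bootstrap": 200,
        "upstream_length": 1000,
        "d_range": [3, 500],
        "pad_zeros": 50000,
        "period_band": [140, 200],
        "expression_quantile": 0.2,
        "n_meth_bins": 5,
        "max_gap": 20,
        "tss_window": 500,
        "occupancy_window": 200,
        "occupancy_flank": 2000,
        "occupancy_resamples": 50,
    },
    "inputs": {},
}

_STAGE_OFFSETS = {
    "features": 101,
    "phylo": 102,
    "tss": 103,
}


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> dict:
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for key, val in raw.items():
        if isinstance(cfg.get(key), dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{key} must be a mapping")
            cfg[key].update(val)
        else:
            cfg[key] = val
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    for name, path in (cfg.get("inputs") or {}).items():
        if not Path(path).exists():
            raise ConfigError(f"input {name!r} not found: {path}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def run(config: dict, outdir) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    params = cfg["params"]
    stages = cfg["stages"]
    outputs: dict[str, Path] = {}
    manifest: dict = {"seed": seed, "stages": [], "params": params}

    def _stage(name: str):
        manifest["stages"].append(name)

    # -- simulate -----------------------------------------------------------
    _stage("simulate")
    sim_cfg = syn_mod.SimConfig.preset(
        cfg["simulate"]["preset"], seed=seed, **cfg["simulate"]["overrides"]
    )
    sim = syn_mod.simulate_all(sim_cfg)
    simdir = out / "simulated"
    for name, path in syn_mod.write_all(sim, simdir).items():
        outputs[f"simulated/{name}"] = Path(path)

    annotation = sim.annotation
    if stages["annotation"]:
        _stage("annotation")
        annotation = ann_mod.derive_introns(annotation)
        annotation = ann_mod.derive_upstream(annotation, params["upstream_length"])
        annotation = ann_mod.screen_overlaps(annotation)
        p = out / "annotation.gff3"
        ann_mod.write_gff3(annotation, p)
        outputs["annotation.gff3"] = p

    filtered = sites_mod.filter_sites(sim.sample, params["min_coverage"])
    spike_filtered = sites_mod.filter_sites(sim.spike, params["min_coverage"])
    if stages["sites"]:
        _stage("sites")
        nonconv = sites_mod.estimate_nonconversion(spike_filtered)
        summary = {
            "n_sites_raw": len(sim.sample),
            "n_sites_filtered": len(filtered),
            "nonconversion": {
                "rate": nonconv.rate, "ci_low": nonconv.ci_low, "ci_high": nonconv.ci_high,
            },
            "global_mean_fraction_percent": sites_mod.genomewide_methylation(
                filtered, "mean_fraction"
            ).percent,
            "global_binomial_percent": sites_mod.genomewide_methylation(
                filtered, "binomial_vs_spike", nonconversion=max(nonconv.rate, 1e-6)
            ).percent,
        }
        cmp_res = sites_mod.compare_to_spikein(filtered, spike_filtered)
        summary["spike_comparison"] = {
            "difference": cmp_res.difference, "z": cmp_res.z, "p": cmp_res.p,
        }
        p = out / "sites_summary.json"
        _write_json(summary, p)
        outputs["sites_summary.json"] = p

    gene_means = None
    high_genes = low_genes = None
    if stages["features"]:
        _stage("features")
        fseed = seed + _STAGE_OFFSETS["features"]
        summary: dict = {}
        class_rows = []
        meths_by_class = {}
        for fclass in ("exon", "intron", "TE", "upstream"):
            ivs = annotation.intervals(fclass)
            if not ivs:
                continue
            fms = feat_mod.feature_mean_methylation(ivs, filtered, params["min_cpgs"])
            meths_by_class[fclass] = fms
            defined = [f for f in fms if f.defined]
            if defined:
                cs = feat_mod.class_summary(defined, params["bootstrap"], seed=fseed)
                class_rows.append((fclass, cs.mean, cs.ci_low, cs.ci_high, cs.n_features))
        bg = ann_mod.background_mask(annotation, 0)
        summary["background_mean"] = feat_mod.background_mean(bg, filtered)
        summary["classes"] = [
            {"class": c, "mean": m, "ci_low": lo, "ci_high": hi, "n": n}
            for c, m, lo, hi, n in class_rows
        ]
        gene_means = expr_mod.gene_mean_from_features(meths_by_class.get("exon", []))
        if len(gene_means) >= 2:
            cl = feat_mod.cluster_high_low(gene_means.to_numpy())
            summary["gene_proportion_high"] = cl.proportion_high
            k = max(1, int(round(params["expression_quantile"] * len(gene_means))))
            ranked = gene_means.sort_values(ascending=False, kind="mergesort")
            high_genes = list(ranked.index[:k])
            low_genes = list(ranked.index[-k:])
        te_fms = meths_by_class.get("TE", [])
        te_vals = np.array([f.mean_methylation for f in te_fms if f.defined])
        if len(te_vals) >= 2:
            summary["te_proportion_high"] = feat_mod.cluster_high_low(te_vals).proportion_high
        prof = feat_mod.metagene(
            annotation.intervals("TE"), filtered, contig_lengths=annotation.contig_lengths
        )
        pd.DataFrame(
            {"bin": np.arange(len(prof.means)), "mean": prof.means, "n": prof.counts}
        ).to_csv(out / "metagene_te.tsv", sep="\t", index=False, float_format="%.6g")
        outputs["metagene_te.tsv"] = out / "metagene_te.tsv"
        gene_means.rename_axis("gene").to_csv(
            out / "gene_methylation.tsv", sep="\t", float_format="%.6g"
        )
        outputs["gene_methylation.tsv"] = out / "gene_methylation.tsv"
        p = out / "features_summary.json"
        _write_json(summary, p)
        outputs["features_summary.json"] = p

    if stages["periodicity"]:
        _stage("periodicity")
        dmin, dmax = params["d_range"]
        result = {}
        for fclass in ("exon", "intron"):
            ivs = annotation.intervals(fclass)
            if not ivs:
                continue
            profile = per_mod.correlation_by_distance(filtered, ivs, (dmin, dmax))
            if profile.defined.sum() < 10:
                continue
            resid = per_mod.detrend(profile)
            spec = per_mod.spectrum(resid, params["pad_zeros"])
            band = tuple(params["period_band"])
            result[fclass] = {
                "band_intensity": per_mod.band_score(spec, band),
                "dominant_period": per_mod.dominant_period(spec, band),
            }
            pd.DataFrame(
                {"d": profile.d, "r": profile.r, "n_pairs": profile.n_pairs}
            ).to_csv(out / f"correlation_{fclass}.tsv", sep="\t", index=False,
                     float_format="%.6g")
            outputs[f"correlation_{fclass}.tsv"] = out / f"correlation_{fclass}.tsv"
        p = out / "periodicity.json"
        _write_json(result, p)
        outputs["periodicity.json"] = p

    if stages["phylo"]:
        _stage("phylo")
        asr = phylo_mod.asr_bm(sim.tree, sim.tip_values)
        asr.table.to_csv(out / "ancestral_states.tsv", sep="\t", float_format="%.8g")
        outputs["ancestral_states.tsv"] = out / "ancestral_states.tsv"
        rng = np.random.default_rng(seed + _STAGE_OFFSETS["phylo"])
        pred = pd.DataFrame(
            {"alkb2": rng.integers(0, 2, size=sim.tree.n_tips())},
            index=sim.tree.tip_labels,
        )
        if pred["alkb2"].nunique() > 1:
            res = phylo_mod.pgls(sim.tree, sim.tip_values, pred)
            res.table.to_csv(out / "pgls.tsv", sep="\t", float_format="%.8g")
            outputs["pgls.tsv"] = out / "pgls.tsv"

    if stages["expression"] and high_genes:
        _stage("expression")
        summary = {}
        expr = sim.expression
        cv = expr_mod.tissue_cv(expr)
        contrast = expr_mod.cv_contrast(cv, high_genes, low_genes)
        summary["cv_contrast"] = {
            "median_high_meth": contrast.median_high,
            "median_low_meth": contrast.median_low,
            "p": contrast.p,
        }
        up_means = expr_mod.gene_mean_from_features(
            feat_mod.feature_mean_methylation(
                annotation.intervals("upstream"), filtered, params["min_cpgs"]
            )
        )
        if len(up_means) >= 10:
            binned = expr_mod.upstream_meth_expression(up_means, expr, params["n_meth_bins"])
            summary["upstream_bins"] = {
                "medians": binned.medians, "p": binned.p,
            }
        hk = set(sim.methylome.gene_classes.loc[
            sim.methylome.gene_classes["methylated"], "gene"
        ])
        try:
            enr = expr_mod.housekeeping_enrichment(high_genes, low_genes, hk)
            summary["housekeeping"] = {
                "table": enr.table, "odds_ratio": enr.odds_ratio, "p": enr.p,
            }
        except ValueError:
            pass
        counts = expr_mod.gene_exon_counts(annotation.gene_exons())
        ec = expr_mod.exon_count_contrast(gene_means, counts)
        summary["exon_count_contrast"] = {
            "mean_single": ec.mean_single, "mean_multi": ec.mean_multi, "p": ec.p,
        }
        p = out / "expression_summary.json"
        _write_json(summary, p)
        outputs["expression_summary.json"] = p

    if stages["tss"] and high_genes:
        _stage("tss")
        summary = {}
        ctss = tss_mod.tpm_normalize(sim.ctss)
        clusters = tss_mod.cluster_ctss(ctss, params["max_gap"])
        tssmap = syn_mod.gene_tss(annotation)
        assigned = tss_mod.assign_clusters_to_genes(clusters, tssmap, params["tss_window"])
        wc = tss_mod.width_contrast(assigned, high_genes, low_genes)
        summary["width_contrast"] = {
            "median_high_meth": wc.median_high, "median_low_meth": wc.median_low, "p": wc.p,
        }
        sub = {g: tssmap[g] for g in (set(high_genes) | set(low_genes)) if g in tssmap}
        meta = tss_mod.occupancy_metagene(
            sim.occupancy, sub,
            window=params["occupancy_window"], flank=params["occupancy_flank"],
            resamples=params["occupancy_resamples"],
            seed=seed + _STAGE_OFFSETS["tss"],
        )
        pd.DataFrame(
            {
                "center": meta.window_centers, "mean": meta.mean,
                "smooth": meta.smooth, "band_low": meta.band_low,
                "band_high": meta.band_high,
            }
        ).to_csv(out / "occupancy_metagene.tsv", sep="\t", index=False, float_format="%.6g")
        outputs["occupancy_metagene.tsv"] = out / "occupancy_metagene.tsv"
        p = out / "tss_summary.json"
        _write_json(summary, p)
        outputs["tss_summary.json"] = p

    manifest["outputs"] = {name: _sha256(path) for name, path in sorted(outputs.items())}
    manifest["param_hash"] = hashlib.sha256(
        json.dumps(_jsonable(params), sort_keys=True).encode()
    ).hexdigest()
    _write_json(manifest, out / "manifest.json")
    return manifest
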