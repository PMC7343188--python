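# arthromethyl

A comparative CpG-methylome analysis toolkit. It re-implements, as a tested
and reusable pipeline, the core analyses of a cross-species DNA-methylation
study: per-CpG bisulfite call filtering and genome-wide summaries,
feature-level methylation with bootstrap confidence intervals and high/low
clustering, metagene and exon-rank profiles, nucleosome-length periodicity
detection in CpG-pair correlation (correlation-by-distance → linear detrend
→ zero-padded FFT → 140–200 bp band intensity), Brownian-motion
maximum-likelihood ancestral state reconstruction and phylogenetic GLS,
expression/housekeeping integration (FPKM, tissue CV, within-species
z-score coupling, Fisher enrichment, orthogroup ranking), and CAGE TSS
shape analysis (tag clustering, interquantile width, nucleosome-occupancy
metagenes with resampled loess bands).

A first-class synthetic-data module generates annotated multi-contig
genomes, class-structured true methylomes with nucleosome-phased sites,
binomial bisulfite counts with non-conversion error and an unmethylated
spike-in, BM-evolving tip traits on a tree, tissue-structured expression,
CTSS tags and occupancy tracks — so every downstream stage is testable
offline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the oracle/property acceptance suite
(brute-force pair-correlation oracle, naive-DFT oracle, period recovery at
implanted repeat lengths, re-rooting GLS oracle for ancestral states, PGLS
type-I calibration, hand-counted filter fixtures, mixture-proportion
recovery, CTSS hand traces, end-to-end architecture checks, pipeline
determinism).

## CLI

Every stage is a subcommand of `arthromethyl`:

```sh
# synthetic dataset (GFF3, cytosine report, spike-in, tree, expression,
# CTSS BED, occupancy bedGraph)
arthromethyl simulate --preset strigamia-like --seed 1 --out sim/

# derived annotation features
arthromethyl annotate derive-introns  --gff sim/genome.gff3 --out introns.gff3
arthromethyl annotate derive-upstream --gff sim/genome.gff3 --out up.gff3 --upstream-length 1000
arthromethyl annotate screen          --gff up.gff3 --out screened.gff3

# site-level summaries
arthromethyl sites filter --in sim/cytosine_report.tsv --out filtered.tsv --min-cov 10
arthromethyl sites spike  --in sim/spike_report.tsv
arthromethyl sites global --in sim/cytosine_report.tsv --caller mean_fraction

# feature methylation, clustering, metagenes
arthromethyl featmeth summarize --gff sim/genome.gff3 --sites sim/cytosine_report.tsv \
    --class exon --min-cpgs 3 --bootstrap 1000 --seed 1 --out exons.tsv
arthromethyl featmeth metagene  --gff sim/genome.gff3 --sites sim/cytosine_report.tsv --class TE --out mg.tsv

# nucleosome periodicity
arthromethyl periodicity --gff sim/genome.gff3 --sites sim/cytosine_report.tsv \
    --class exon --dmin 3 --dmax 500 --pad 50000 --band 140:200

# comparative phylogenetics
arthromethyl phylo asr  --tree sim/tree.nwk --traits sim/tip_values.tsv --out asr.tsv
arthromethyl phylo pgls --tree tree.nwk --traits traits.tsv --response trait --predictors alkb2 --out pgls.tsv

# expression integration and TSS shape
arthromethyl expr fpkm --counts counts.tsv --lengths lengths.tsv --total-mapped 1e7 --out fpkm.tsv
arthromethyl expr cv --expr sim/expression.tsv --out cv.tsv
arthromethyl tss cluster --ctss sim/ctss.bed --max-gap 20 --q 0.1:0.9 --out clusters.tsv
arthromethyl tss metagene --track sim/occupancy.bedgraph --gff sim/genome.gff3 --out occ.tsv

# full pipeline from one YAML config
arthromethyl run --config run.yaml --out results/
```

Minimal `run.yaml`:

```yaml
seed: 1
simulate:
  preset: strigamia-like
  overrides: {n_genes: 60, n_tes: 30}
params:
  bootstrap: 500
```

Reruns with the same config and seed produce byte-identical outputs; a
`manifest.json` records seeds, parameters and sha256 checksums.

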