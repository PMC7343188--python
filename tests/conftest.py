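import numpy as np
import pandas as pd
import pytest

from arthromethyl.annotation import GenomeAnnotation, Interval
from arthromethyl.phylo import PhyloTree
from arthromethyl.sites import SiteTable


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """One contig, two genes (one multi-exon), one TE, rRNA/tRNA."""
    ann = GenomeAnnotation({"c1": 10_000, "c2": 8_500})
    ann.add(Interval("c1", 2000, 3000, "+", "gene", id="gA"))
    ann.add(Interval("c1", 2000, 2200, "+", "exon", parent="gA", id="gA.e1"))
    ann.add(Interval("c1", 2400, 2700, "+", "exon", parent="gA", id="gA.e2"))
    ann.add(Interval("c1", 2900, 3000, "+", "exon", parent="gA", id="gA.e3"))
    ann.add(Interval("c2", 5000, 8000, "-", "gene", id="gB"))
    ann.add(Interval("c2", 5000, 8000, "-", "exon", parent="gB", id="gB.e1"))
    ann.add(Interval("c1", 6000, 7000, "+", "TE", id="te1"))
    ann.add(Interval("c1", 8000, 8100, ".", "rRNA", id="r1"))
    ann.add(Interval("c1", 9000, 9050, ".", "tRNA", id="t1"))
    return ann


def make_site_table(records) -> SiteTable:
    """records: (contig, pos, meth_plus, total_plus, meth_minus, total_minus)."""
    return SiteTable(
        pd.DataFrame(
            records,
            columns=["contig", "pos", "meth_plus", "total_plus", "meth_minus", "total_minus"],
        )
    )


def random_tree(n_tips: int, rng: np.random.Generator, labels=None) -> PhyloTree:
    """Random rooted binary tree with uniform(0.1, 2) branch lengths."""
    if labels is None:
        labels = [f"t{i}" for i in range(n_tips)]
    subtrees = [lab for lab in labels]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b1, b2 = rng.uniform(0.1, 2.0, size=2)
        merged = f"({subtrees[i]}:{b1:.6f},{subtrees[j]}:{b2:.6f})"
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [merged]
    return PhyloTree.from_newick(subtrees[0] + ";")
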