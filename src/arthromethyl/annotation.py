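"""Genome annotations: typed intervals, GFF3/BED I/O and derived features.

Coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted at the I/O boundary.  Feature classes follow a fixed vocabulary
(gene, exon, intron, UTR, upstream, TE, rRNA, tRNA).  Secondary features
(introns, upstream windows) are derived, not read, and TEs/upstream regions
can be screened against overlapping annotations.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

FEATURE_CLASSES = ("gene", "exon", "intron", "UTR", "upstream", "TE", "rRNA", "tRNA")

#: GFF3 column-3 types accepted for each internal feature class.
GFF3_TYPE_MAP = {
    "gene": "gene",
    "exon": "exon",
    "intron": "intron",
    "five_prime_UTR": "UTR",
    "three_prime_UTR": "UTR",
    "UTR": "UTR",
    "upstream_region": "upstream",
    "upstream": "upstream",
    "transposable_element": "TE",
    "repeat_region": "TE",
    "TE": "TE",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
}

#: Canonical GFF3 type emitted for each internal feature class.
GFF3_TYPE_OUT = {
    "gene": "gene",
    "exon": "exon",
    "intron": "intron",
    "UTR": "UTR",
    "upstream": "upstream_region",
    "TE": "transposable_element",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
}


class AnnotationError(ValueError):
    """Malformed annotation input or inconsistent feature structure."""


@dataclass(frozen=True, order=True)
class Interval:
    """A strand-aware genomic interval (0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str = "."
    feature_class: str = "gene"
    parent: str | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """Strand-blind overlap: at least one shared base."""
        return self.contig == other.contig and self.start < other.end and other.start < self.end


class GenomeAnnotation:
    """Container of typed intervals per contig with a gene -> exon hierarchy."""

    def __init__(
        self,
        contig_lengths: Mapping[str, int],
        intervals: Iterable[Interval] = (),
    ) -> None:
        self.contig_lengths: dict[str, int] = dict(contig_lengths)
        self._by_class: dict[str, list[Interval]] = {c: [] for c in FEATURE_CLASSES}
        for iv in intervals:
            self.add(iv)

    def add(self, iv: Interval) -> None:
        if iv.feature_class not in self._by_class:
            raise AnnotationError(f"unknown feature class {iv.feature_class!r}")
        clen = self.contig_lengths.get(iv.contig)
        if clen is None:
            raise AnnotationError(f"unknown contig {iv.contig!r}")
        if iv.end > clen:
            raise AnnotationError(
                f"interval [{iv.start},{iv.end}) exceeds contig {iv.contig} length {clen}"
            )
        self._by_class[iv.feature_class].append(iv)

    def intervals(self, feature_class: str | None = None, contig: str | None = None) -> list[Interval]:
        if feature_class is None:
            out = [iv for c in FEATURE_CLASSES for iv in self._by_class[c]]
        else:
            if feature_class not in self._by_class:
                raise AnnotationError(f"unknown feature class {feature_class!r}")
            out = list(self._by_class[feature_class])
        if contig is not None:
            out = [iv for iv in out if iv.contig == contig]
        return sorted(out)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_class.values())

    def gene_exons(self) -> dict[str, list[Interval]]:
        """Map gene id -> exons sorted by start; every exon's parent must exist."""
        genes = {g.id for g in self._by_class["gene"]}
        out: dict[str, list[Interval]] = {g.id: [] for g in self._by_class["gene"]}
        for ex in self._by_class["exon"]:
            if ex.parent is None or ex.parent not in genes:
                raise AnnotationError(f"exon {ex} has no known parent gene")
            out[ex.parent].append(ex)
        for g in out:
            out[g].sort()
        return out

    def replace_class(self, feature_class: str, intervals: Iterable[Interval]) -> "GenomeAnnotation":
        """New annotation with one feature class swapped out."""
        new = GenomeAnnotation(self.contig_lengths)
        for c in FEATURE_CLASSES:
            source = intervals if c == feature_class else self._by_class[c]
            for iv in source:
                new.add(iv)
        return new

    def copy(self) -> "GenomeAnnotation":
        new = GenomeAnnotation(self.contig_lengths)
        for c in FEATURE_CLASSES:
            for iv in self._by_class[c]:
                new.add(iv)
        return new


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_annotation(
    path,
    format: str = "GFF3",
    contig_lengths: Mapping[str, int] | None = None,
    feature_class: str = "TE",
) -> GenomeAnnotation:
    """Read a GFF3 (or BED6) annotation into internal 0-based coordinates.

    Genes whose exons land on more than one contig are dropped with a
    warning.  Contig lengths come from ``##sequence-region`` pragmas, a
    ``contig_lengths`` mapping, or default to the maximum observed end.
    For BED input every record is assigned ``feature_class``.
    """
    fmt = format.upper()
    if fmt == "BED":
        return _read_bed(path, contig_lengths=contig_lengths, feature_class=feature_class)
    if fmt != "GFF3":
        raise AnnotationError(f"unknown annotation format {format!r}")

    lengths: dict[str, int] = dict(contig_lengths or {})
    raw: list[Interval] = []
    max_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _src, ftype, start1, end1, _score, strand, _phase, attr = cols
            cls = GFF3_TYPE_MAP.get(ftype)
            if cls is None:
                continue
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad coordinates") from exc
            if start < 0 or end <= start:
                raise AnnotationError(f"{path}:{lineno}: invalid span {start1}..{end1}")
            attrs = _parse_gff3_attributes(attr)
            if cls == "exon" and "Parent" not in attrs:
                raise AnnotationError(f"{path}:{lineno}: exon without Parent attribute")
            iv = Interval(
                contig=contig,
                start=start,
                end=end,
                strand=strand if strand in ("+", "-") else ".",
                feature_class=cls,
                parent=attrs.get("Parent"),
                id=attrs.get("ID"),
            )
            raw.append(iv)
            max_end[contig] = max(max_end.get(contig, 0), end)

    for contig, end in max_end.items():
        lengths.setdefault(contig, end)

    # Drop genes split across multiple contigs (and their children).
    gene_contigs: dict[str, set[str]] = {}
    for iv in raw:
        gid = iv.id if iv.feature_class == "gene" else iv.parent
        if gid is not None:
            gene_contigs.setdefault(gid, set()).add(iv.contig)
    split = {g for g, cs in gene_contigs.items() if len(cs) > 1}
    if split:
        warnings.warn(
            f"dropping {len(split)} gene(s) split across multiple contigs: "
            + ", ".join(sorted(split)),
            stacklevel=2,
        )
        raw = [
            iv
            for iv in raw
            if (iv.id if iv.feature_class == "gene" else iv.parent) not in split
        ]

    ann = GenomeAnnotation(lengths)
    for iv in raw:
        ann.add(iv)
    return ann


def _read_bed(path, contig_lengths=None, feature_class: str = "TE") -> GenomeAnnotation:
    lengths: dict[str, int] = dict(contig_lengths or {})
    raw: list[Interval] = []
    max_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise AnnotationError(f"{path}:{lineno}: expected >=3 BED columns")
            contig, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            raw.append(
                Interval(contig, start, end, strand, feature_class, id=name)
            )
            max_end[contig] = max(max_end.get(contig, 0), end)
    for contig, end in max_end.items():
        lengths.setdefault(contig, end)
    ann = GenomeAnnotation(lengths)
    for iv in raw:
        ann.add(iv)
    return ann


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write all intervals to GFF3 (deterministic ordering)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in sorted(annotation.contig_lengths):
            fh.write(f"##sequence-region {contig} 1 {annotation.contig_lengths[contig]}\n")
        for iv in sorted(annotation.intervals(), key=lambda v: (v.contig, v.start, v.end, v.feature_class, v.id or "")):
            attrs = []
            if iv.id:
                attrs.append(f"ID={iv.id}")
            if iv.parent:
                attrs.append(f"Parent={iv.parent}")
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        "arthromethyl",
                        GFF3_TYPE_OUT[iv.feature_class],
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand if iv.strand in ("+", "-") else ".",
                        ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


def write_bed6(intervals: Sequence[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.id or iv.feature_class}\t0\t"
                f"{iv.strand if iv.strand in ('+', '-') else '.'}\n"
            )


# ---------------------------------------------------------------------------
# Derived features
# ---------------------------------------------------------------------------

def derive_introns(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Introns fill inter-exon gaps of each multi-exon gene; single-exon genes yield none."""
    introns: list[Interval] = []
    for gid, exons in sorted(annotation.gene_exons().items()):
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise AnnotationError(f"gene {gid}: overlapping exons {a} and {b}")
            if b.start > a.end:
                introns.append(
                    Interval(a.contig, a.end, b.start, a.strand, "intron", parent=gid)
                )
    return annotation.replace_class("intron", introns)


def derive_upstream(annotation: GenomeAnnotation, length: int = 1000) -> GenomeAnnotation:
    """Strand-aware windows immediately 5' of each gene.

    Genes whose window would run past the contig start or end are excluded.
    """
    ups: list[Interval] = []
    for g in annotation.intervals("gene"):
        clen = annotation.contig_lengths[g.contig]
        if g.strand == "-":
            start, end = g.end, g.end + length
        else:
            start, end = g.start - length, g.start
        if start < 0 or end > clen:
            continue
        ups.append(Interval(g.contig, start, end, g.strand, "upstream", parent=g.id))
    return annotation.replace_class("upstream", ups)


def _overlap_index(blockers: Sequence[Interval]):
    """Per-contig sorted (start, end) arrays for overlap queries."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in blockers:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for contig, spans in by_contig.items():
        spans.sort()
        ms: list[int] = []
        me: list[int] = []
        for s, e in spans:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[contig] = (ms, me)
    return merged


def _hits(index, iv: Interval) -> bool:
    got = index.get(iv.contig)
    if got is None:
        return False
    starts, ends = got
    i = bisect_right(starts, iv.start)
    # candidate blocks: the one starting at or before iv.start, and the next
    if i > 0 and ends[i - 1] > iv.start:
        return True
    return i < len(starts) and starts[i] < iv.end


def screen_overlaps(
    annotation: GenomeAnnotation, upstream_against: str = "pre"
) -> GenomeAnnotation:
    """Remove conflicted TEs and upstream windows.

    TEs overlapping any rRNA, tRNA or exon are removed; upstream regions
    overlapping any TE, rRNA, tRNA or exon are removed.  Overlap is one or
    more shared bases, strand-blind.  ``upstream_against`` selects whether
    upstream windows are tested against the pre- or post-screen TE set.
    """
    if upstream_against not in ("pre", "post"):
        raise AnnotationError("upstream_against must be 'pre' or 'post'")
    rre = (
        annotation.intervals("rRNA")
        + annotation.intervals("tRNA")
        + annotation.intervals("exon")
    )
    te_blockers = _overlap_index(rre)
    tes = annotation.intervals("TE")
    kept_tes = [te for te in tes if not _hits(te_blockers, te)]

    te_set = tes if upstream_against == "pre" else kept_tes
    up_blockers = _overlap_index(rre + te_set)
    kept_up = [up for up in annotation.intervals("upstream") if not _hits(up_blockers, up)]

    return annotation.replace_class("TE", kept_tes).replace_class("upstream", kept_up)


def background_mask(annotation: GenomeAnnotation, min_distance: int = 0) -> list[Interval]:
    """Complement of all annotated features, eroded by ``min_distance`` bp.

    With ``min_distance=0`` this is the "outside annotated features"
    background; with 1000 the strict ">1 kb from annotated regions" one.
    """
    if min_distance < 0:
        raise AnnotationError("min_distance must be >= 0")
    index = _overlap_index(annotation.intervals())
    out: list[Interval] = []
    for contig in sorted(annotation.contig_lengths):
        clen = annotation.contig_lengths[contig]
        starts, ends = index.get(contig, ([], []))
        cursor = 0
        for s, e in zip(starts, ends):
            s_pad = max(0, s - min_distance)
            if s_pad > cursor:
                out.append(Interval(contig, cursor, s_pad, ".", "background"))
            cursor = max(cursor, min(clen, e + min_distance))
        if cursor < clen:
            out.append(Interval(contig, cursor, clen, ".", "background"))
    return out
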