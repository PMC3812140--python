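"""Positional classification of lncRNAs relative to a coding-gene catalog.

Each long noncoding RNA (lncRNA) locus is assigned one of six genomic-context
classes by its relation to protein-coding transcripts:

``sense_overlap``
    a lncRNA exon overlaps a coding exon on the same strand;
``intronic``
    the lncRNA's genomic span lies wholly inside one intron of a same-strand
    coding transcript;
``antisense_overlap``
    a lncRNA exon overlaps a coding exon on the opposite strand;
``nonantisense_overlap``
    genomic spans overlap on opposite strands without any exon–exon overlap;
``bidirectional``
    the lncRNA is oriented head-to-head (divergent promoters) with a coding
    transcript, TSS-to-TSS distance within a window (default 1000 bp,
    inclusive), with no span overlap;
``intergenic``
    none of the above.

When several rules match different catalog genes, the highest-precedence class
wins, in the order listed above (exon-level, same-strand evidence dominates
proximity evidence).  For reporting, the six classes collapse to four:
intronic folds into sense_overlap and nonantisense_overlap into
antisense_overlap.

Coordinates are 0-based half-open throughout; GFF3 input (1-based inclusive)
is converted on read.  The transcription start site (TSS) of a '+' locus is
its first exon start; of a '−' locus, its last exon end − 1.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

CLASS6 = (
    "sense_overlap",
    "intronic",
    "antisense_overlap",
    "nonantisense_overlap",
    "bidirectional",
    "intergenic",
)
CLASS4 = ("sense_overlap", "antisense_overlap", "bidirectional", "intergenic")

_PRECEDENCE = {name: i for i, name in enumerate(CLASS6)}

_COLLAPSE = {
    "sense_overlap": "sense_overlap",
    "intronic": "sense_overlap",
    "antisense_overlap": "antisense_overlap",
    "nonantisense_overlap": "antisense_overlap",
    "bidirectional": "bidirectional",
    "intergenic": "intergenic",
}


class AnnotationError(ValueError):
    """Raised for malformed transcript models or annotation files."""


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured locus (coding gene or lncRNA).

    Parameters
    ----------
    id :
        Unique locus identifier.
    chrom :
        Chromosome / contig name.
    strand :
        ``'+'`` or ``'-'``.
    exons :
        Ordered, non-overlapping ``(start, end)`` pairs in 0-based half-open
        genomic coordinates.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise AnnotationError(f"{self.id}: empty exon list")
        for s, e in exons:
            if s >= e:
                raise AnnotationError(f"{self.id}: exon ({s},{e}) has start >= end")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise AnnotationError(f"{self.id}: exons out of order or overlapping")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        """Sum of exon lengths (the transcript length probes interrogate)."""
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]))


@dataclass
class ClassifiedLncRNA:
    lnc_id: str
    class6: str
    partner_gene_id: str | None = None
    tss_distance_bp: int | None = None

    @property
    def class4(self) -> str:
        return _COLLAPSE[self.class6]


def collapse_class(value: str) -> str:
    """Map a six-way positional class onto the four reporting classes."""
    try:
        return _COLLAPSE[value]
    except KeyError:
        raise AnnotationError(f"unknown positional class {value!r}") from None


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _exon_exon_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    # exon lists are sorted: merge-walk instead of all-pairs
    i = j = 0
    while i < len(a.exons) and j < len(b.exons):
        if _intervals_overlap(a.exons[i], b.exons[j]):
            return True
        if a.exons[i][1] <= b.exons[j][1]:
            i += 1
        else:
            j += 1
    return False


def _relation(lnc: TranscriptModel, gene: TranscriptModel, window: int) -> tuple[str, int | None]:
    """Class of *lnc* relative to a single catalog *gene* (+ TSS distance)."""
    if lnc.chrom != gene.chrom:
        return "intergenic", None
    span_overlap = lnc.start < gene.end and gene.start < lnc.end
    same_strand = lnc.strand == gene.strand
    if same_strand:
        if span_overlap and _exon_exon_overlap(lnc, gene):
            return "sense_overlap", None
        for s, e in gene.introns:
            if s <= lnc.start and lnc.end <= e:
                return "intronic", None
        return "intergenic", None
    # opposite strands
    if span_overlap:
        if _exon_exon_overlap(lnc, gene):
            return "antisense_overlap", None
        return "nonantisense_overlap", None
    # divergent head-to-head: the two TSSs face each other across the gap
    if lnc.start >= gene.end:  # gene left of lnc
        divergent = gene.strand == "-" and lnc.strand == "+"
    else:  # lnc left of gene
        divergent = lnc.strand == "-" and gene.strand == "+"
    if divergent:
        d = abs(lnc.tss - gene.tss)
        if d <= window:
            return "bidirectional", d
    return "intergenic", None


class GeneIndex:
    """Interval index over a coding-gene catalog for fast candidate lookup."""

    def __init__(self, catalog: Iterable[TranscriptModel], window: int = 1000):
        self.window = int(window)
        self.genes: list[TranscriptModel] = list(catalog)
        self._trees: dict[str, IntervalTree] = {}
        for k, g in enumerate(self.genes):
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            # pad by window so bidirectional candidates are retrieved too
            tree.addi(g.start - self.window, g.end + self.window, k)

    def candidates(self, lnc: TranscriptModel) -> list[TranscriptModel]:
        tree = self._trees.get(lnc.chrom)
        if tree is None:
            return []
        hits = tree.overlap(lnc.start - 1, lnc.end + 1)
        return [self.genes[h.data] for h in hits]


def classify_one(
    lnc: TranscriptModel,
    catalog: Iterable[TranscriptModel] | GeneIndex,
    window: int = 1000,
) -> ClassifiedLncRNA:
    """Assign a six-way positional class to one lncRNA.

    The highest-precedence matching class over all catalog genes wins
    (sense_overlap > intronic > antisense_overlap > nonantisense_overlap >
    bidirectional > intergenic); partner ties break by smaller TSS distance,
    then lexicographic gene id.  An empty catalog yields ``intergenic``.
    """
    if window < 0:
        raise AnnotationError("window must be >= 0")
    if isinstance(catalog, GeneIndex):
        genes: Iterable[TranscriptModel] = catalog.candidates(lnc)
    else:
        genes = catalog
    best: tuple[int, int, str] | None = None  # (precedence, tss_dist, gene id)
    best_rel: tuple[str, int | None, str] | None = None
    for gene in genes:
        rel, d = _relation(lnc, gene, window)
        if rel == "intergenic":
            continue
        tss_d = abs(lnc.tss - gene.tss)
        key = (_PRECEDENCE[rel], tss_d, gene.id)
        if best is None or key < best:
            best = key
            best_rel = (rel, d, gene.id)
    if best_rel is None:
        return ClassifiedLncRNA(lnc.id, "intergenic")
    rel, d, gid = best_rel
    return ClassifiedLncRNA(lnc.id, rel, gid, d)


def classify_all(
    lncs: Sequence[TranscriptModel],
    catalog: Iterable[TranscriptModel],
    window: int = 1000,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every lncRNA and summarize collapsed-class fractions.

    Returns
    -------
    table : DataFrame
        One row per lncRNA: lnc_id, class6, class4, partner_gene_id,
        tss_distance_bp.
    fractions : Series
        Fraction of lncRNAs per collapsed class (sums to 1); empty for empty
        input.
    """
    ids = [l.id for l in lncs]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise AnnotationError(f"duplicate lnc ids: {list(dup[dup > 1].index[:5])}")
    index = catalog if isinstance(catalog, GeneIndex) else GeneIndex(catalog, window)
    rows = []
    for lnc in lncs:
        c = classify_one(lnc, index, window)
        rows.append((c.lnc_id, c.class6, c.class4, c.partner_gene_id, c.tss_distance_bp))
    table = pd.DataFrame(
        rows, columns=["lnc_id", "class6", "class4", "partner_gene_id", "tss_distance_bp"]
    )
    if len(table):
        fractions = (
            table["class4"].value_counts(normalize=True).reindex(CLASS4, fill_value=0.0)
        )
    else:
        fractions = pd.Series(dtype=float)
    return table, fractions


# ---------------------------------------------------------------------------
# I/O: GFF3 / BED12 readers, TSV / BED6 writers
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from a GFF3 file (gene/transcript + exon rows).

    Exons are grouped by their ``Parent`` attribute; a feature with no exon
    children becomes a single-exon model.  1-based inclusive GFF coordinates
    are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    seen: set[str] = set()
    for ftype in ("transcript", "mRNA", "gene"):
        for feat in db.features_of_type(ftype):
            if feat.id in seen:
                continue
            exons = sorted(
                (c.start - 1, c.end) for c in db.children(feat, featuretype="exon")
            )
            if not exons:
                exons = [(feat.start - 1, feat.end)]
            models.append(TranscriptModel(feat.id, feat.seqid, feat.strand, tuple(exons)))
            seen.add(feat.id)
    return models


def write_gff3(models: Iterable[TranscriptModel], path: str | os.PathLike, source: str = "lnccompartment") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chrom}\t{source}\ttranscript\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\tID={m.id}\n"
            )
            for k, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.id}.exon{k};Parent={m.id}\n"
                )


def read_bed12(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from BED12 (block fields give exon structure)."""
    models = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path}:{ln}: BED12 requires 12 fields, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise AnnotationError(f"{path}:{ln}: blockCount mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(starts, sizes))
            models.append(TranscriptModel(name, chrom, strand, exons))
    return models


def write_classification_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_class_beds(
    lncs: Sequence[TranscriptModel], table: pd.DataFrame, outdir: str | os.PathLike
) -> dict[str, str]:
    """Write one BED6 file per collapsed class for genome-browser use."""
    os.makedirs(outdir, exist_ok=True)
    by_id = {l.id: l for l in lncs}
    paths = {}
    for cls in CLASS4:
        sub = table[table["class4"] == cls]
        path = os.path.join(str(outdir), f"lnc_{cls}.bed")
        with open(path, "w") as fh:
            for lnc_id in sub["lnc_id"]:
                m = by_id[lnc_id]
                fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.id}\t0\t{m.strand}\n")
        paths[cls] = path
    return paths
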