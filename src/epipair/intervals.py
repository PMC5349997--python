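"""Genomic coordinate conventions, interval arithmetic and annotation I/O.

All coordinates are 0-based, half-open ``[start, end)`` internally.  BED input
is taken as-is; GTF features (1-based, closed) are converted on ingest.
Overlap is strand-blind throughout: MeDIP reads and peaks carry no usable
strand, and every downstream overlap rule (peak-to-element, DMR-to-gene)
inherits that convention.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GeneElements",
    "AnnotationBundle",
    "GenomeIndex",
    "ELEMENT_CLASSES",
    "derive_elements",
    "merge_intervals",
    "interval_union_length",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "read_bed12_gene_models",
    "read_gtf_gene_models",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fasta",
    "write_fasta",
]

#: Gene element classes derived from a gene model, in transcript order.
ELEMENT_CLASSES = ("promoter", "utr5", "cds", "intron", "utr3")


class FileFormatError(ValueError):
    """Raised for malformed records; message names file and line number."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind: shares >= 1 base with ``other``."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class GeneModel:
    """One transcript model per gene: transcript span, coding span, exons.

    ``cds_start == cds_end`` marks a non-coding gene.  Exons are sorted,
    disjoint and contained in ``[tx_start, tx_end)``.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid tx/cds nesting")
        prev_end = None
        for s, e in self.exons:
            if s >= e or s < self.tx_start or e > self.tx_end:
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) out of bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end


@dataclass(frozen=True)
class GeneElements:
    """Per-gene element intervals: promoter, 5'-UTR, CDS, intron, 3'-UTR."""

    gene_id: str
    element_map: Mapping[str, tuple[GenomicInterval, ...]]

    def intervals(self, element_class: str) -> tuple[GenomicInterval, ...]:
        return self.element_map.get(element_class, ())


@dataclass
class AnnotationBundle:
    """Everything the distribution and classification stages need.

    CpG islands and repeats are annotation *inputs* (the pipeline does not
    detect them); repeats carry a repeat-class label in ``name``.
    """

    genes: dict[str, GeneModel]
    elements: dict[str, GeneElements]
    cpg_islands: list[GenomicInterval]
    repeats: list[GenomicInterval]
    chrom_sizes: dict[str, int]

    def validate(self) -> None:
        for iv in list(self.cpg_islands) + list(self.repeats):
            size = self.chrom_sizes.get(iv.chrom)
            if size is None or iv.end > size:
                raise ValueError(f"interval {iv} outside chrom_sizes bounds")
        for g in self.genes.values():
            size = self.chrom_sizes.get(g.chrom)
            if size is None or g.tx_end > size:
                raise ValueError(f"gene {g.gene_id} outside chrom_sizes bounds")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted disjoint set covering the same bases, per chromosome.

    Touching half-open intervals ``[a,b)`` and ``[b,c)`` merge into ``[a,c)``
    (union-of-covered-bases semantics, as required when merging paired peak
    sets into candidate DMRs).  Strand and names are dropped.
    """
    by_chrom: dict[str, list[GenomicInterval]] = collections.defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or touch
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def interval_union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total number of distinct bases covered."""
    return sum(iv.length for iv in merge_intervals(intervals))


class GenomeIndex:
    """Per-chromosome interval index for strand-blind overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees[iv.chrom].addi(iv.start, iv.end, iv)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlap_query(self, query: GenomicInterval) -> list[GenomicInterval]:
        """Subject intervals sharing >= 1 base with ``query``.

        An unknown chromosome yields an empty list.  Results are sorted by
        (start, end) for determinism.
        """
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(query.start, query.end)]
        hits.sort(key=lambda iv: (iv.start, iv.end, iv.name))
        return hits

    def overlaps_any(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        return bool(tree is not None and tree.overlap(query.start, query.end))


# ---------------------------------------------------------------------------
# Gene element derivation
# ---------------------------------------------------------------------------

def derive_elements(
    gene: GeneModel,
    promoter_len: int = 2000,
    chrom_length: int | None = None,
) -> GeneElements:
    """Split a gene model into promoter / 5'-UTR / CDS / intron / 3'-UTR.

    The promoter is ``promoter_len`` bp immediately upstream of the
    strand-aware transcription start, clipped to chromosome bounds.  The
    5'-UTR is the exonic sequence between the transcript start and the coding
    start (strand-aware); the 3'-UTR is symmetric; the CDS is the exonic
    intersection with the coding span; introns are the gaps between
    consecutive exons.  For a coding gene the exonic bases partition exactly
    into utr5 + cds + utr3.  Non-coding genes get empty utr5/cds/utr3 but
    still a promoter and introns.
    """
    if promoter_len <= 0:
        raise ValueError("promoter_len must be positive")
    gid, chrom = gene.gene_id, gene.chrom

    def clip(s: int, e: int) -> tuple[int, int]:
        s = max(s, 0)
        if chrom_length is not None:
            e = min(e, chrom_length)
        return s, e

    if gene.strand == "+":
        ps, pe = clip(gene.tx_start - promoter_len, gene.tx_start)
    else:
        ps, pe = clip(gene.tx_end, gene.tx_end + promoter_len)
    promoter = (
        (GenomicInterval(chrom, ps, pe, gene.strand, gid),) if ps < pe else ()
    )

    introns = []
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if e1 < s2:
            introns.append(GenomicInterval(chrom, e1, s2, gene.strand, gid))

    def exonic_within(lo: int, hi: int) -> tuple[GenomicInterval, ...]:
        out = []
        for s, e in gene.exons:
            s2, e2 = max(s, lo), min(e, hi)
            if s2 < e2:
                out.append(GenomicInterval(chrom, s2, e2, gene.strand, gid))
        return tuple(out)

    if gene.is_coding:
        cds = exonic_within(gene.cds_start, gene.cds_end)
        left = exonic_within(gene.tx_start, gene.cds_start)
        right = exonic_within(gene.cds_end, gene.tx_end)
        utr5, utr3 = (left, right) if gene.strand == "+" else (right, left)
    else:
        cds = utr5 = utr3 = ()

    return GeneElements(
        gene_id=gid,
        element_map={
            "promoter": promoter,
            "utr5": utr5,
            "cds": cds,
            "intron": tuple(introns),
            "utr3": utr3,
        },
    )


# ---------------------------------------------------------------------------
# File formats: BED, BED12, GTF, chrom.sizes, FASTA
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (0-based half-open, BED native)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else ""
                strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
                out.append(GenomicInterval(chrom, start, end, strand, name))
            except (IndexError, ValueError) as exc:
                raise FileFormatError(f"{path}:{lineno}: malformed BED line: {exc}")
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], *, score=None) -> None:
    """Write BED6 (name/score/strand columns filled from each interval)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{0 if score is None else score}\t{iv.strand}\n"
            )


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            try:
                sizes[f[0]] = int(f[1])
            except (IndexError, ValueError) as exc:
                raise FileFormatError(f"{path}:{lineno}: malformed chrom.sizes: {exc}")
    return sizes


def write_chrom_sizes(path, sizes: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed12_gene_models(path) -> dict[str, GeneModel]:
    """Read gene models from BED12 (one transcript per gene_id, column 4)."""
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end, gid = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5]
                thick_s, thick_e = int(f[6]), int(f[7])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple(
                    (start + o, start + o + sz) for o, sz in zip(offsets, sizes)
                )
                genes[gid] = GeneModel(
                    gid, chrom, strand, start, end, thick_s, thick_e, exons
                )
            except (IndexError, ValueError) as exc:
                raise FileFormatError(f"{path}:{lineno}: malformed BED12 line: {exc}")
    return genes


def read_gtf_gene_models(path) -> dict[str, GeneModel]:
    """Read gene models from GTF (exon/CDS features, grouped by gene_id).

    GTF coordinates are 1-based closed; converted to 0-based half-open on
    ingest.  One model per gene_id: the union span of its exons.
    """
    import gffutils

    exons: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    cds: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    meta: dict[str, tuple[str, str]] = {}
    try:
        for feat in gffutils.DataIterator(str(path)):
            try:
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise FileFormatError(
                    f"{path}: feature without gene_id attribute: {feat}"
                ) from exc
            start, end = feat.start - 1, feat.end  # 1-based closed -> half-open
            if feat.featuretype == "exon":
                exons[gid].append((start, end))
                meta[gid] = (feat.seqid, feat.strand)
            elif feat.featuretype == "CDS":
                cds[gid].append((start, end))
    except FileFormatError:
        raise
    except Exception as exc:  # malformed line inside gffutils
        raise FileFormatError(f"{path}: malformed GTF: {exc}") from exc
    genes: dict[str, GeneModel] = {}
    for gid, ex in exons.items():
        chrom, strand = meta[gid]
        merged = merge_intervals(GenomicInterval(chrom, s, e) for s, e in ex)
        ex_t = tuple((iv.start, iv.end) for iv in merged)
        tx_s, tx_e = ex_t[0][0], ex_t[-1][1]
        if gid in cds:
            cds_s = min(s for s, _ in cds[gid])
            cds_e = max(e for _, e in cds[gid])
        else:
            cds_s = cds_e = tx_s
        genes[gid] = GeneModel(gid, chrom, strand, tx_s, tx_e, cds_s, cds_e, ex_t)
    return genes


def read_gene_models(path) -> dict[str, GeneModel]:
    """Dispatch on extension: .gtf/.gff -> GTF dialect, otherwise BED12."""
    p = str(path)
    if p.endswith((".gtf", ".gff")):
        return read_gtf_gene_models(path)
    return read_bed12_gene_models(path)


def write_bed12(path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offs = ",".join(str(s - g.tx_start) for s, _ in g.exons) + ","
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.cds_start}\t{g.cds_end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Read a (desk-scale) FASTA into an in-memory dict of upper-case strings."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Vectorised overlap helpers shared by QC and DMR stages
# ---------------------------------------------------------------------------

def intervals_to_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) arrays sorted by start."""
    by_chrom: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        out[chrom] = (arr[:, 0].copy(), arr[:, 1].copy())
    return out


def count_overlaps_disjoint(
    regions: Sequence[GenomicInterval],
    items: Sequence[GenomicInterval],
) -> np.ndarray:
    """For disjoint sorted ``regions``, count items overlapping each by >= 1 bp.

    An item spanning several regions counts once in each.  Used for read
    counting over candidate DMRs, where regions are disjoint by construction.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    region_idx: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[int]] = collections.defaultdict(list)
    for i, r in enumerate(regions):
        by_chrom[r.chrom].append(i)
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: regions[i].start)
        starts = np.array([regions[i].start for i in idxs], dtype=np.int64)
        ends = np.array([regions[i].end for i in idxs], dtype=np.int64)
        region_idx[chrom] = (starts, ends, np.asarray(idxs, dtype=np.int64))

    items_by_chrom = intervals_to_arrays(items)
    for chrom, (it_s, it_e) in items_by_chrom.items():
        if chrom not in region_idx:
            continue
        r_s, r_e, idxs = region_idx[chrom]
        lo = np.searchsorted(r_e, it_s, side="right")
        hi = np.searchsorted(r_s, it_e, side="left")
        # item j overlaps regions lo[j] .. hi[j]-1
        diff = np.zeros(len(r_s) + 1, dtype=np.int64)
        valid = hi > lo
        np.add.at(diff, lo[valid], 1)
        np.add.at(diff, hi[valid], -1)
        counts[idxs] += np.cumsum(diff[:-1])
    return counts
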