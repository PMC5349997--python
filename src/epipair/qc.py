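"""Read filtering and MeDIP-seq distribution statistics.

Covers the descriptive QC layer of the methylome analysis: FASTQ-level read
filtering (undetermined-base and low-quality rules), cytosine context
classification (CpG / CHG / CHH), depth-of-coverage profiles, CpG-density
binning, gene-element distributions and metagene profiles around anchors
such as CpG islands or gene bodies.

Alignment itself is external: aligned reads arrive as genomic intervals
(BED), and every distribution here is computed exactly, per base, which is
the right trade-off at desk-scale genome sizes.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .intervals import (
    ELEMENT_CLASSES,
    AnnotationBundle,
    GenomicInterval,
    intervals_to_arrays,
    merge_intervals,
)

__all__ = [
    "ReadRecord",
    "FilterReport",
    "ContextSiteSet",
    "DepthProfile",
    "ElementDistribution",
    "read_fastq",
    "filter_reads",
    "classify_contexts",
    "coverage_by_depth",
    "density_binned_distribution",
    "element_distribution",
    "metagene_profile",
    "peak_length_distribution",
]

PHRED_OFFSET = 33  # Sanger/Illumina 1.8+ encoding


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """A sequencing read with per-base Phred scores.

    Q = -10*log10(per-base error rate); scores must be non-negative and as
    long as the sequence.
    """

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id}: negative Phred score")


@dataclass
class FilterReport:
    total: int = 0
    kept: int = 0
    removed_n_rule: int = 0
    removed_quality_rule: int = 0

    @property
    def removed(self) -> int:
        return self.total - self.kept


def read_fastq(path) -> Iterator[ReadRecord]:
    """Parse FASTQ (Phred+33) into ReadRecords."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            rec.id,
            str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
        )


def filter_reads(
    reads: Iterable[ReadRecord],
    max_n_frac: float = 0.10,
    low_q: int = 20,
    max_lowq_frac: float = 0.50,
) -> tuple[list[ReadRecord], FilterReport]:
    """Remove undetermined-base and low-quality reads.

    A read is removed iff its fraction of N bases exceeds ``max_n_frac``
    (strict >), or the fraction of bases with Phred quality <= ``low_q``
    (inclusive) exceeds ``max_lowq_frac`` (strict >).  A read failing both
    rules is attributed to the N rule in the report.  The decision is
    per-read, so filtering is order-independent.
    """
    kept: list[ReadRecord] = []
    report = FilterReport()
    for read in reads:
        report.total += 1
        n = len(read.sequence)
        n_frac = read.sequence.count("N") / n
        lowq_frac = sum(1 for q in read.qualities if q <= low_q) / n
        if n_frac > max_n_frac:
            report.removed_n_rule += 1
        elif lowq_frac > max_lowq_frac:
            report.removed_quality_rule += 1
        else:
            kept.append(read)
            report.kept += 1
    return kept, report


# ---------------------------------------------------------------------------
# Cytosine context classification
# ---------------------------------------------------------------------------

@dataclass
class ContextSiteSet:
    """Positions of cytosines by context, per chromosome and strand.

    ``sites[chrom][strand]`` maps context label ("CpG", "CHG", "CHH") to a
    sorted numpy array of 0-based positions of the C (on that strand).
    Labels are mutually exclusive per (position, strand).
    """

    sites: dict[str, dict[str, dict[str, np.ndarray]]]

    def positions(self, chrom: str, context: str) -> np.ndarray:
        """All positions of ``context`` on either strand of ``chrom``, sorted."""
        per = self.sites.get(chrom, {})
        arrs = [per.get(s, {}).get(context, np.empty(0, np.int64)) for s in "+-"]
        return np.sort(np.concatenate(arrs))

    def count(self, context: str) -> int:
        return sum(len(self.positions(c, context)) for c in self.sites)


_H = frozenset(b"ACT")


def classify_contexts(genome: Mapping[str, str]) -> ContextSiteSet:
    """Classify every cytosine into CpG / CHG / CHH on both strands.

    Plus strand: a C at i is CpG if base i+1 is G; CHG if i+1 is H and i+2
    is G; CHH if i+1 and i+2 are both H (H in {A,C,T}).  Minus-strand
    contexts are read on the reverse complement, i.e. a G at i on the plus
    strand is a minus-strand C whose downstream bases are the complements of
    i-1, i-2.  Cytosines lacking two downstream bases are unclassified; N is
    never a context base (H excludes N), so CHG/CHH calls involving an
    undetermined base are suppressed.
    """
    out: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        n = len(arr)
        is_g = arr == ord("G")
        is_h = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("T"))
        plus: dict[str, np.ndarray] = {}
        minus: dict[str, np.ndarray] = {}
        if n >= 3:
            c = arr[: n - 2] == ord("C")
            b1g, b1h = is_g[1 : n - 1], is_h[1 : n - 1]
            b2g, b2h = is_g[2:], is_h[2:]
            plus["CpG"] = np.flatnonzero(c & b1g)
            plus["CHG"] = np.flatnonzero(c & b1h & b2g)
            plus["CHH"] = np.flatnonzero(c & b1h & b2h)
            # minus strand: C is a plus-strand G; downstream bases are the
            # complements of positions i-1, i-2, so "G" maps to a plus C and
            # "H" to a plus base in {A,G,T}
            comp_h = (
                (arr == ord("A")) | (arr == ord("G")) | (arr == ord("T"))
            )
            g = arr[2:] == ord("G")
            u1c, u1h = arr[1 : n - 1] == ord("C"), comp_h[1 : n - 1]
            u2c, u2h = arr[: n - 2] == ord("C"), comp_h[: n - 2]
            minus["CpG"] = np.flatnonzero(g & u1c) + 2
            minus["CHG"] = np.flatnonzero(g & u1h & u2c) + 2
            minus["CHH"] = np.flatnonzero(g & u1h & u2h) + 2
        out[chrom] = {"+": plus, "-": minus}
    return ContextSiteSet(out)


# ---------------------------------------------------------------------------
# Depth and distribution statistics
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Fractions of the genome covered at depth == d and >= d, d = 1..max."""

    genome_size: int
    frac_eq: dict[int, float]
    frac_ge: dict[int, float]

    @property
    def max_depth(self) -> int:
        return max(self.frac_eq, default=0)


def _per_base_depth(
    intervals: Sequence[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> dict[str, np.ndarray]:
    depths = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_sizes.items()}
    for chrom, (starts, ends) in intervals_to_arrays(intervals).items():
        if chrom not in depths:
            continue
        size = len(depths[chrom])
        diff = np.zeros(size + 1, dtype=np.int64)
        np.add.at(diff, np.clip(starts, 0, size), 1)
        np.add.at(diff, np.clip(ends, 0, size), -1)
        depths[chrom] = np.cumsum(diff[:-1]).astype(np.int32)
    return depths


def coverage_by_depth(
    reads: Sequence[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> DepthProfile:
    """Exact per-base genome-coverage distribution across sequencing depth."""
    genome_size = sum(chrom_sizes.values())
    counts = collections.Counter()
    for depth in _per_base_depth(reads, chrom_sizes).values():
        vals, cnts = np.unique(depth, return_counts=True)
        for v, c in zip(vals.tolist(), cnts.tolist()):
            counts[v] += c
    max_d = max((d for d in counts if d > 0), default=0)
    frac_eq, frac_ge = {}, {}
    running = 0
    for d in range(max_d, 0, -1):
        running += counts.get(d, 0)
        frac_eq[d] = counts.get(d, 0) / genome_size
        frac_ge[d] = running / genome_size
    return DepthProfile(genome_size, dict(sorted(frac_eq.items())),
                        dict(sorted(frac_ge.items())))


def density_binned_distribution(
    items: Sequence[GenomicInterval],
    sites: ContextSiteSet,
    bin_edges: Sequence[float] = (0, 1, 2, 3, 4, 5, 7, 10, 15, 20),
    context: str = "CpG",
) -> dict[tuple[float, float], int]:
    """Histogram of items by CpG density (sites per 100 bp).

    Density = (number of context sites whose C falls inside the item) * 100
    / item length.  The last bin is open-ended; values below the first edge
    fall in the first bin.
    """
    edges = list(bin_edges) + [float("inf")]
    hist = {(edges[i], edges[i + 1]): 0 for i in range(len(edges) - 1)}
    pos_cache = {
        chrom: sites.positions(chrom, context)
        for chrom in {it.chrom for it in items}
    }
    for it in items:
        pos = pos_cache.get(it.chrom, np.empty(0, np.int64))
        k = int(np.searchsorted(pos, it.end) - np.searchsorted(pos, it.start))
        density = k * 100.0 / it.length
        for i in range(len(edges) - 1):
            if density < edges[i + 1] or i == len(edges) - 2:
                hist[(edges[i], edges[i + 1])] += 1
                break
    return hist


@dataclass
class ElementDistribution:
    """Per element class: item count (>=1 bp overlap) and base coverage.

    One item may count in several classes (e.g. a peak spanning a
    CDS/intron junction); coverage is the number of class bases the items
    cover at least once, so it never exceeds the class's total length.
    """

    counts: dict[str, int]
    coverage_bp: dict[str, int]
    element_length_bp: dict[str, int]


def _class_intervals(annotation: AnnotationBundle) -> dict[str, list[GenomicInterval]]:
    classes: dict[str, list[GenomicInterval]] = {
        "cpg_island": list(annotation.cpg_islands),
    }
    for cls in ELEMENT_CLASSES:
        classes[cls] = [
            iv
            for el in annotation.elements.values()
            for iv in el.intervals(cls)
        ]
    for rep in annotation.repeats:
        classes.setdefault(f"repeat:{rep.name or 'unknown'}", []).append(rep)
    # intergenic = complement of gene spans and promoters
    genic = [
        GenomicInterval(g.chrom, g.tx_start, g.tx_end)
        for g in annotation.genes.values()
    ] + classes["promoter"]
    merged = merge_intervals(genic) if genic else []
    by_chrom: dict[str, list[GenomicInterval]] = collections.defaultdict(list)
    for iv in merged:
        by_chrom[iv.chrom].append(iv)
    intergenic = []
    for chrom, size in annotation.chrom_sizes.items():
        prev = 0
        for iv in by_chrom.get(chrom, []):
            if prev < iv.start:
                intergenic.append(GenomicInterval(chrom, prev, iv.start))
            prev = iv.end
        if prev < size:
            intergenic.append(GenomicInterval(chrom, prev, size))
    classes["intergenic"] = intergenic
    return classes


def element_distribution(
    items: Sequence[GenomicInterval], annotation: AnnotationBundle
) -> ElementDistribution:
    """Distribution of items (reads or peaks) across gene elements.

    Classes: CpG island, promoter, 5'-UTR, CDS, intron, 3'-UTR, repeat
    classes, intergenic.
    """
    classes = _class_intervals(annotation)
    counts: dict[str, int] = {}
    coverage: dict[str, int] = {}
    lengths: dict[str, int] = {}
    items_by_chrom = intervals_to_arrays(items)
    for cls, ivs in classes.items():
        merged = merge_intervals(ivs) if ivs else []
        lengths[cls] = sum(iv.length for iv in merged)
        cls_by_chrom = intervals_to_arrays(merged)
        n_items = 0
        cov = 0
        for chrom, (c_s, c_e) in cls_by_chrom.items():
            if chrom not in items_by_chrom:
                continue
            it_s, it_e = items_by_chrom[chrom]
            # count items overlapping any class interval
            lo = np.searchsorted(c_e, it_s, side="right")
            hi = np.searchsorted(c_s, it_e, side="left")
            n_items += int(np.count_nonzero(hi > lo))
            # covered class bases: union of items intersected with class
            size = int(max(c_e.max(), it_e.max()))
            diff = np.zeros(size + 1, dtype=np.int8)
            np.add.at(diff, it_s.clip(0, size), 1)
            np.add.at(diff, it_e.clip(0, size), -1)
            item_mask = np.cumsum(diff[:-1]) > 0
            cls_mask = np.zeros(size, dtype=bool)
            for s, e in zip(c_s, c_e):
                cls_mask[s:e] = True
            cov += int(np.count_nonzero(item_mask & cls_mask))
        counts[cls] = n_items
        coverage[cls] = cov
    return ElementDistribution(counts, coverage, lengths)


def metagene_profile(
    items: Sequence[GenomicInterval],
    anchors: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    flank_bp: int = 2000,
    n_body_bins: int = 40,
    n_flank_bins: int = 20,
) -> np.ndarray:
    """Mean per-base item depth around scaled anchor regions.

    Each anchor is rescaled to ``n_body_bins`` bins; the fixed-width flanks
    get ``n_flank_bins`` bins each.  Minus-strand anchors are reversed so
    the profile reads 5'->3'.  Returns an array of length
    ``2*n_flank_bins + n_body_bins`` of depths averaged over anchors.
    """
    depth = _per_base_depth(items, chrom_sizes)
    total_bins = 2 * n_flank_bins + n_body_bins
    acc = np.zeros(total_bins)
    n_used = 0
    for anchor in anchors:
        d = depth.get(anchor.chrom)
        if d is None:
            continue
        size = len(d)
        prof = np.zeros(total_bins)
        # upstream flank (genomic left for + strand)
        up = np.zeros(flank_bp)
        lo, hi = anchor.start - flank_bp, anchor.start
        src = d[max(lo, 0) : max(hi, 0)]
        up[flank_bp - len(src) :] = src
        down = np.zeros(flank_bp)
        lo, hi = anchor.end, anchor.end + flank_bp
        src = d[min(lo, size) : min(hi, size)]
        down[: len(src)] = src
        body = d[anchor.start : anchor.end].astype(float)
        if anchor.strand == "-":
            up, down = down[::-1], up[::-1]
            body = body[::-1]
        prof[:n_flank_bins] = _bin_means(up, n_flank_bins)
        prof[n_flank_bins : n_flank_bins + n_body_bins] = _bin_means(body, n_body_bins)
        prof[n_flank_bins + n_body_bins :] = _bin_means(down, n_flank_bins)
        acc += prof
        n_used += 1
    return acc / n_used if n_used else acc


def _bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    if len(values) == 0:
        return np.zeros(n_bins)
    edges = np.linspace(0, len(values), n_bins + 1)
    out = np.empty(n_bins)
    for i in range(n_bins):
        lo, hi = int(edges[i]), max(int(edges[i + 1]), int(edges[i]) + 1)
        out[i] = values[lo : min(hi, len(values))].mean() if lo < len(values) else 0.0
    return out


def peak_length_distribution(
    peaks: Sequence[GenomicInterval], bin_width: int = 100
) -> dict[tuple[int, int], int]:
    """Histogram of peak lengths in fixed-width bins ``[k*w, (k+1)*w)``."""
    hist: dict[tuple[int, int], int] = {}
    for p in peaks:
        k = p.length // bin_width
        key = (k * bin_width, (k + 1) * bin_width)
        hist[key] = hist.get(key, 0) + 1
    return dict(sorted(hist.items()))
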