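"""Paired DMR calling: candidate regions, chi-square testing, DMG classes.

The inference chain for one case/control pair:

1. the pair's MeDIP peak sets are merged (union of covered bases) into
   disjoint *candidate DMRs*;
2. each candidate gets the number of reads from each sample overlapping it
   by >= 1 bp, and a Pearson chi-square test (1 df, no continuity
   correction) on the 2x2 table of in-region vs rest-of-library reads;
3. a candidate is a *true DMR* when raw p <= 0.01, FDR-adjusted q <= 0.01,
   and the library-size-normalized read ratio exceeds 2-fold;
4. uptrend means the case (e.g. epileptic) sample has the higher normalized
   rate, downtrend the control;
5. per gene element, a gene is hyper-methylated when the element overlaps
   only uptrend true DMRs, hypo-methylated when only downtrend, mixed when
   both.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import (
    ELEMENT_CLASSES,
    GeneElements,
    GenomicInterval,
    GenomeIndex,
    count_overlaps_disjoint,
    merge_intervals,
)

__all__ = [
    "PeakSet",
    "CandidateDMR",
    "DMRResult",
    "DMGRecord",
    "build_candidates",
    "chi_square_test",
    "chi_square_tests",
    "call_true_dmrs",
    "classify_dmgs",
    "summarize_dmrs",
    "fdr_adjust",
]


@dataclass
class PeakSet:
    """One sample's MACS-style peak calls plus its library size.

    ``library_size`` is the sample's total uniquely mapped read count; it is
    the normalization denominator for fold changes and the margin of the
    chi-square table.
    """

    sample_id: str
    peaks: list[GenomicInterval]
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError(f"{self.sample_id}: library_size must be > 0")
        self.peaks = merge_intervals(self.peaks) if self.peaks else []


@dataclass(frozen=True, slots=True)
class CandidateDMR:
    region: GenomicInterval
    count_case: int
    count_control: int
    lib_case: int
    lib_control: int

    def __post_init__(self) -> None:
        if self.count_case < 0 or self.count_control < 0:
            raise ValueError("read counts must be >= 0")


@dataclass(frozen=True, slots=True)
class DMRResult:
    candidate: CandidateDMR
    chi2_stat: float
    p_value: float
    q_value: float
    fold: float
    trend: str  # "uptrend" | "downtrend" | "none"
    is_true_dmr: bool

    @property
    def region(self) -> GenomicInterval:
        return self.candidate.region


@dataclass(frozen=True)
class DMGRecord:
    """Per (gene, element class) methylation call from overlapping true DMRs."""

    gene_id: str
    element_class: str
    status: str  # hyper | hypo | mixed | unmethylated
    supporting_dmrs: tuple[str, ...] = ()


def build_candidates(
    case_peaks: PeakSet,
    control_peaks: PeakSet,
    case_reads: Sequence[GenomicInterval],
    control_reads: Sequence[GenomicInterval],
) -> list[CandidateDMR]:
    """Merge the pair's peaks into candidate DMRs and count reads per region.

    Candidate regions are the union of covered bases of both samples' peaks
    (disjoint by construction); each read contributes to every region it
    overlaps by >= 1 bp.
    """
    all_peaks = list(case_peaks.peaks) + list(control_peaks.peaks)
    if not all_peaks:
        return []
    regions = merge_intervals(all_peaks)
    n_case = count_overlaps_disjoint(regions, case_reads)
    n_control = count_overlaps_disjoint(regions, control_reads)
    return [
        CandidateDMR(r, int(a), int(b), case_peaks.library_size,
                     control_peaks.library_size)
        for r, a, b in zip(regions, n_case, n_control)
    ]


def chi_square_tests(
    count_case: np.ndarray,
    count_control: np.ndarray,
    lib_case: np.ndarray | int,
    lib_control: np.ndarray | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson chi-square (1 df) on 2x2 enrichment tables.

    Table per region: ``[[count_case, lib_case - count_case],
    [count_control, lib_control - count_control]]``; no Yates correction;
    p from the upper tail.  Regions with both counts zero get stat 0, p 1.
    """
    a = np.asarray(count_case, dtype=float)
    b = np.asarray(count_control, dtype=float)
    n1 = np.broadcast_to(np.asarray(lib_case, dtype=float), a.shape)
    n2 = np.broadcast_to(np.asarray(lib_control, dtype=float), a.shape)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("library sizes must be > 0")
    if np.any(a > n1) or np.any(b > n2):
        raise ValueError("region count exceeds library size")
    total = a + b
    n = n1 + n2
    # Pearson statistic for the 2x2 table with fixed margins:
    # X^2 = N (ad - bc)^2 / (row1 row2 col1 col2)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = n * (a * (n2 - b) - b * (n1 - a)) ** 2
        den = n1 * n2 * total * (n - total)
        stat = np.where(total > 0, num / den, 0.0)
    stat = np.nan_to_num(stat, nan=0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(total > 0, p, 1.0)
    return stat, p


def chi_square_test(c: CandidateDMR) -> tuple[float, float]:
    """Chi-square test for a single candidate DMR (see chi_square_tests)."""
    stat, p = chi_square_tests(
        np.array([c.count_case]), np.array([c.count_control]),
        c.lib_case, c.lib_control,
    )
    return float(stat[0]), float(p[0])


def fdr_adjust(p_values: np.ndarray, method: str = "bh") -> np.ndarray:
    """Step-up FDR-adjusted p-values (Benjamini-Hochberg or -Yekutieli)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if method not in ("bh", "by"):
        raise ValueError(f"unknown FDR method {method!r}")
    return stats.false_discovery_control(p, method=method)


def _fold_and_trend(
    count_case, count_control, lib_case, lib_control, pseudocount: float = 0.5
):
    """Normalized fold >= 1 and trend per region.

    rate ratio r = (count_case/lib_case) / (count_control/lib_control);
    fold = max(r, 1/r).  The pseudocount is added to *both* counts only when
    one of them is zero, keeping the fold finite without touching the test.
    """
    a = np.asarray(count_case, dtype=float)
    b = np.asarray(count_control, dtype=float)
    zero = (a == 0) | (b == 0)
    a = np.where(zero, a + pseudocount, a)
    b = np.where(zero, b + pseudocount, b)
    rate_case = a / lib_case
    rate_ctrl = b / lib_control
    r = rate_case / rate_ctrl
    fold = np.maximum(r, 1.0 / r)
    trend = np.where(r > 1, "uptrend", np.where(r < 1, "downtrend", "none"))
    return fold, trend


def call_true_dmrs(
    candidates: Sequence[CandidateDMR],
    p_max: float = 0.01,
    fold_min: float = 2.0,
    fdr_method: str = "bh",
    pseudocount: float = 0.5,
) -> list[DMRResult]:
    """Test all candidates of a pair and flag true DMRs.

    True DMR iff raw p <= ``p_max`` AND FDR-adjusted q <= ``p_max`` AND
    normalized fold strictly > ``fold_min``.  q-values are computed over all
    candidates of the pair.  Regions with zero reads in both samples are
    untestable and never true DMRs.
    """
    if not candidates:
        return []
    a = np.array([c.count_case for c in candidates])
    b = np.array([c.count_control for c in candidates])
    lib1 = np.array([c.lib_case for c in candidates], dtype=float)
    lib2 = np.array([c.lib_control for c in candidates], dtype=float)
    stat, p = chi_square_tests(a, b, lib1, lib2)
    q = fdr_adjust(p, method=fdr_method)
    fold, trend = _fold_and_trend(a, b, lib1, lib2, pseudocount)
    testable = (a + b) > 0
    is_true = testable & (p <= p_max) & (q <= p_max) & (fold > fold_min)
    return [
        DMRResult(c, float(stat[i]), float(p[i]), float(q[i]), float(fold[i]),
                  str(trend[i]), bool(is_true[i]))
        for i, c in enumerate(candidates)
    ]


def classify_dmgs(
    dmrs: Sequence[DMRResult],
    elements: Mapping[str, GeneElements] | Iterable[GeneElements],
) -> list[DMGRecord]:
    """Classify each (gene, element class) by the trend of overlapping DMRs.

    hyper: the element overlaps only uptrend true DMRs; hypo: only
    downtrend; mixed: both; unmethylated: none.  The classification depends
    only on the overlap topology, so input order is irrelevant.
    """
    if isinstance(elements, Mapping):
        element_list = list(elements.values())
    else:
        element_list = list(elements)
    true_dmrs = [d for d in dmrs if d.is_true_dmr]
    up_idx = GenomeIndex(d.region for d in true_dmrs if d.trend == "uptrend")
    down_idx = GenomeIndex(d.region for d in true_dmrs if d.trend == "downtrend")

    def dmr_id(iv: GenomicInterval) -> str:
        return f"{iv.chrom}:{iv.start}-{iv.end}"

    records = []
    for el in element_list:
        for cls in ELEMENT_CLASSES:
            ivs = el.intervals(cls)
            if not ivs:
                continue
            up_hits = {dmr_id(h) for iv in ivs for h in up_idx.overlap_query(iv)}
            down_hits = {dmr_id(h) for iv in ivs for h in down_idx.overlap_query(iv)}
            if up_hits and down_hits:
                status = "mixed"
            elif up_hits:
                status = "hyper"
            elif down_hits:
                status = "hypo"
            else:
                status = "unmethylated"
            records.append(
                DMGRecord(el.gene_id, cls, status,
                          tuple(sorted(up_hits | down_hits)))
            )
    return records


def summarize_dmrs(
    dmrs_by_pair: Mapping[str, Sequence[DMRResult]],
    dmgs_by_pair: Mapping[str, Sequence[DMGRecord]] | None = None,
) -> tuple[dict[str, dict[str, float]], dict[tuple[str, str], int]]:
    """Per-pair true-DMR counts/coverage and a per-chromosome DMG presence
    matrix (the tabular equivalent of a Circos track).
    """
    per_pair: dict[str, dict[str, float]] = {}
    presence: dict[tuple[str, str], int] = collections.defaultdict(int)
    for pair_id, dmrs in dmrs_by_pair.items():
        true = [d for d in dmrs if d.is_true_dmr]
        per_pair[pair_id] = {
            "n_candidates": len(dmrs),
            "n_true_dmrs": len(true),
            "covered_bp": sum(d.region.length for d in true),
            "n_uptrend": sum(d.trend == "uptrend" for d in true),
            "n_downtrend": sum(d.trend == "downtrend" for d in true),
        }
        for d in true:
            presence[(pair_id, d.region.chrom)] += 1
    return per_pair, dict(presence)
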