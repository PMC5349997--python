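"""Methylation-expression integration.

Joins per-pair gene-element methylation status (hyper / hypo / unmethylated
from DMR overlap) with per-pair expression change (log2 RPKM ratio,
case/control) and tabulates the distribution of expression change per
(element class, methylation status) stratum.  Genes with zero RPKM on
either side have no finite ratio; they are excluded from the distributions
and counted separately.  "Mixed" elements (overlapping both uptrend and
downtrend DMRs) are reported but sit outside the three-way
hyper/hypo/unmethylated comparison.
"""

from __future__ import annotations

import collections
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dmr import DMGRecord
from .expression import PairwiseDEGResult

__all__ = ["MethExprRecord", "integrate", "ratio_distribution"]


@dataclass(frozen=True, slots=True)
class MethExprRecord:
    gene_id: str
    pair_id: str
    element_class: str
    meth_status: str  # hyper | hypo | mixed | unmethylated
    log2_rpkm_ratio: float  # NaN when either RPKM is zero


def integrate(
    dmgs_by_pair: Mapping[str, Sequence[DMGRecord]],
    expression: Sequence[PairwiseDEGResult],
) -> list[MethExprRecord]:
    """Join per-pair DMG status with per-pair expression ratios on (gene, pair).

    One record per (gene, pair, element class) present on the methylation
    side with an expression measurement for the same gene and pair.  The
    ratio is NaN (excluded from distributions downstream) when either RPKM
    is zero.
    """
    expr_by_pair_gene: dict[tuple[str, str], PairwiseDEGResult] = {
        (r.pair_id, r.gene_id): r for r in expression
    }
    records: list[MethExprRecord] = []
    for pair_id, dmgs in dmgs_by_pair.items():
        for dmg in dmgs:
            expr = expr_by_pair_gene.get((pair_id, dmg.gene_id))
            if expr is None:
                continue
            if expr.rpkm_case > 0 and expr.rpkm_control > 0:
                ratio = math.log2(expr.rpkm_case / expr.rpkm_control)
            else:
                ratio = float("nan")
            records.append(
                MethExprRecord(dmg.gene_id, pair_id, dmg.element_class,
                               dmg.status, ratio)
            )
    return records


def ratio_distribution(
    records: Sequence[MethExprRecord],
    bin_width: float = 1.0,
    value_range: tuple[float, float] = (-10.0, 10.0),
) -> pd.DataFrame:
    """Fraction of genes per log2-ratio bin, per (element, status) stratum.

    Out-of-range ratios clamp into the edge bins; per stratum the fractions
    sum to 1.  Records with a non-finite ratio (zero RPKM on either side)
    are tallied in ``n_excluded`` and contribute no fraction.  Strata with
    no finite ratios are emitted with zero totals.
    """
    lo, hi = value_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    by_stratum: dict[tuple[str, str], list[float]] = collections.defaultdict(list)
    excluded: dict[tuple[str, str], int] = collections.defaultdict(int)
    for r in records:
        key = (r.element_class, r.meth_status)
        if math.isfinite(r.log2_rpkm_ratio):
            by_stratum[key].append(r.log2_rpkm_ratio)
        else:
            excluded[key] += 1
            by_stratum[key]  # ensure stratum appears even if all excluded
    rows = []
    for (element, status), values in sorted(by_stratum.items()):
        total = len(values)
        if total:
            idx = np.clip(
                np.floor((np.asarray(values) - lo) / bin_width).astype(int),
                0, n_bins - 1,
            )
            counts = np.bincount(idx, minlength=n_bins)
        else:
            counts = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            rows.append(
                {
                    "element": element,
                    "status": status,
                    "bin_lo": float(edges[b]),
                    "bin_hi": float(edges[b + 1]),
                    "count": int(counts[b]),
                    "fraction": counts[b] / total if total else 0.0,
                    "n_total": total,
                    "n_excluded": excluded[(element, status)],
                }
            )
    return pd.DataFrame(
        rows, columns=["element", "status", "bin_lo", "bin_hi", "count",
                       "fraction", "n_total", "n_excluded"],
    )
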