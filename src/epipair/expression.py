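"""RPKM expression levels and pairwise exact-test DEG calling.

Expression is quantified as RPKM = 1e9 * count / (library_size *
gene_length_bp).  Per case/control pair, each gene's counts are compared
with the Audic-Claverie exact conditional test for two sequencing
libraries: conditional on observing x counts in library 1 (size N1), the
count y in library 2 (size N2) follows

    P(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1+N2/N1)^(x+y+1))

and the two-sided p-value is min(1, 2*min(P(Y <= y), P(Y >= y))).  The
p-values of one pair are adjusted with the Benjamini-Yekutieli (2001)
step-up procedure (valid under arbitrary dependence) and a gene is called
differentially expressed when FDR <= 0.001 and the RPKM ratio exceeds
2-fold.  Calls are then aggregated across pairs (a gene "in >= k of n
pairs") and expression patterns clustered by Euclidean distance.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.special import gammaln, logsumexp

__all__ = [
    "ExpressionMatrix",
    "PairwiseDEGResult",
    "AggregatedDEG",
    "ClusterResult",
    "rpkm",
    "pairwise_count_test",
    "pairwise_count_tests",
    "by_fdr",
    "call_pairwise_degs",
    "aggregate_across_pairs",
    "intersect_gene_list",
    "cluster_degs",
    "read_counts_tsv",
    "read_pair_manifest",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample read counts with gene lengths and library sizes.

    ``library_size[s]`` is the number of reads uniquely mapped to genes in
    sample ``s`` (defaults to the column sum); gene lengths are in bp.
    """

    counts: pd.DataFrame  # genes x samples, integer counts
    gene_lengths: pd.Series  # bp, indexed like counts
    library_sizes: pd.Series  # indexed by sample

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if (self.gene_lengths <= 0).any() or self.gene_lengths.isna().any():
            raise ValueError("gene lengths must be > 0 for every gene")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.library_sizes <= 0).any() or self.library_sizes.isna().any():
            raise ValueError("library sizes must be > 0 for every sample")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, gene_lengths: pd.Series,
                    library_sizes: pd.Series | None = None) -> "ExpressionMatrix":
        if library_sizes is None:
            library_sizes = counts.sum(axis=0)
        return cls(counts, gene_lengths, library_sizes)

    def rpkm_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            rpkm(
                self.counts.to_numpy(dtype=float),
                self.gene_lengths.to_numpy(dtype=float)[:, None],
                self.library_sizes.to_numpy(dtype=float)[None, :],
            ),
            index=self.counts.index,
            columns=self.counts.columns,
        )


@dataclass(frozen=True, slots=True)
class PairwiseDEGResult:
    gene_id: str
    pair_id: str
    count_case: int
    count_control: int
    rpkm_case: float
    rpkm_control: float
    log2_ratio: float
    p_value: float
    fdr: float
    call: str  # up | down | none


@dataclass(frozen=True, slots=True)
class AggregatedDEG:
    gene_id: str
    n_pairs_called: int
    n_up: int
    n_down: int
    calls: tuple[int, ...]  # +1 up / -1 down / 0 none, one per pair


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix (merge i, merge j, height, size)
    leaf_order: list[str]
    metric: str = "euclidean"
    method: str = "average"


def rpkm(count, gene_length_bp, library_size):
    """Reads per kilobase of gene model per million mapped reads.

    RPKM = 1e9 * count / (library_size * gene_length_bp); accepts scalars or
    broadcastable arrays.
    """
    length = np.asarray(gene_length_bp, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library_size must be > 0")
    if np.any(length <= 0):
        raise ValueError("gene_length_bp must be > 0")
    out = 1e9 * np.asarray(count, dtype=float) / (lib * length)
    return float(out) if np.isscalar(count) else out


# ---------------------------------------------------------------------------
# Exact conditional test for two libraries (Audic & Claverie 1997)
# ---------------------------------------------------------------------------

def _ac_log_pmf_cumulative(x: int, r: float, y_max: int) -> np.ndarray:
    """log P(Y = j | x) for j = 0..y_max, with r = N2/N1."""
    j = np.arange(y_max + 1)
    return (
        j * np.log(r)
        + gammaln(x + j + 1)
        - gammaln(x + 1)
        - gammaln(j + 1)
        - (x + j + 1) * np.log1p(r)
    )


def pairwise_count_test(x: int, y: int, N1: float, N2: float) -> float:
    """Two-sided exact conditional p-value for counts x (case) vs y (control).

    Under the null of equal per-read rates, conditional on x the count y is
    negative-binomially distributed with parameters set by the library-size
    ratio r = N2/N1.  Tails are summed exactly in log space; p = min(1,
    2*min(P(Y <= y), P(Y >= y))).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be >= 0")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be > 0")
    r = N2 / N1
    logpmf = _ac_log_pmf_cumulative(x, r, y)
    log_lower = logsumexp(logpmf)  # P(Y <= y)
    lower = min(np.exp(log_lower), 1.0)
    # upper tail P(Y >= y) = 1 - P(Y <= y-1)
    if y == 0:
        upper = 1.0
    else:
        upper = max(1.0 - min(np.exp(logsumexp(logpmf[:-1])), 1.0), 0.0)
        upper = max(upper, float(np.exp(logpmf[-1])))  # guard cancellation
    return min(1.0, 2.0 * min(lower, upper))


def pairwise_count_tests(
    x: np.ndarray, y: np.ndarray, N1: float, N2: float
) -> np.ndarray:
    """Vectorised pairwise_count_test over gene count vectors."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    out = np.empty(len(x), dtype=float)
    for i in range(len(x)):
        out[i] = pairwise_count_test(int(x[i]), int(y[i]), N1, N2)
    return out


def _chi2_count_test(x, y, N1, N2) -> np.ndarray:
    """2x2 chi-square fallback for the two-library comparison."""
    from .dmr import chi_square_tests

    _, p = chi_square_tests(np.asarray(x), np.asarray(y), N1, N2)
    return p


def by_fdr(p_values) -> np.ndarray:
    """Benjamini-Yekutieli (2001) step-up adjusted p-values.

    adj_(i) = min_{j >= i} min(1, m * c(m) * p_(j) / j) on sorted p-values,
    with the harmonic correction c(m) = sum_{i=1..m} 1/i, mapped back to the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="by")


# ---------------------------------------------------------------------------
# DEG calling and aggregation
# ---------------------------------------------------------------------------

def call_pairwise_degs(
    matrix: ExpressionMatrix,
    pairs: Sequence[tuple[str, str, str]],
    fdr_max: float = 0.001,
    fold_min: float = 2.0,
    test: str = "exact",
) -> list[PairwiseDEGResult]:
    """Per pair, test every gene and call DEGs.

    ``pairs`` is a sequence of (pair_id, case_sample, control_sample).  For
    each pair, genes with zero counts in both samples are excluded from
    testing (and from the FDR family m).  A gene is called up/down when its
    BY-adjusted p <= ``fdr_max`` and its RPKM ratio (either direction) is
    strictly > ``fold_min``; direction follows the RPKM ratio.
    """
    if test not in ("exact", "chi2"):
        raise ValueError(f"unknown test {test!r}")
    results: list[PairwiseDEGResult] = []
    rpkms = matrix.rpkm_matrix()
    for pair_id, case_s, control_s in pairs:
        x = matrix.counts[case_s].to_numpy(dtype=np.int64)
        y = matrix.counts[control_s].to_numpy(dtype=np.int64)
        N1 = float(matrix.library_sizes[case_s])
        N2 = float(matrix.library_sizes[control_s])
        testable = (x + y) > 0
        if test == "exact":
            p_test = pairwise_count_tests(x[testable], y[testable], N1, N2)
        else:
            p_test = _chi2_count_test(x[testable], y[testable], N1, N2)
        fdr_test = by_fdr(p_test)
        p = np.ones(len(x))
        fdr = np.ones(len(x))
        p[testable] = p_test
        fdr[testable] = fdr_test
        r_case = rpkms[case_s].to_numpy()
        r_ctrl = rpkms[control_s].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_ratio = np.log2(r_case) - np.log2(r_ctrl)
        for i, gene in enumerate(matrix.counts.index):
            call = "none"
            if testable[i] and fdr[i] <= fdr_max:
                rc, rk = r_case[i], r_ctrl[i]
                # RPKM ratio in either direction; a zero on one side with a
                # positive other side is an infinite fold.
                if rc > rk and (rk == 0 or rc / rk > fold_min):
                    call = "up"
                elif rk > rc and (rc == 0 or rk / rc > fold_min):
                    call = "down"
            results.append(
                PairwiseDEGResult(
                    str(gene), pair_id, int(x[i]), int(y[i]),
                    float(r_case[i]), float(r_ctrl[i]), float(log2_ratio[i]),
                    float(p[i]), float(fdr[i]), call,
                )
            )
    return results


def aggregate_across_pairs(
    results: Sequence[PairwiseDEGResult],
    pair_ids: Sequence[str],
    k_min: int = 5,
) -> list[AggregatedDEG]:
    """Aggregate per-pair calls into per-gene ternary vectors.

    Returns genes called (either direction) in >= ``k_min`` pairs, with the
    +1/-1/0 call vector ordered like ``pair_ids``.
    """
    pair_pos = {p: i for i, p in enumerate(pair_ids)}
    calls: dict[str, list[int]] = collections.defaultdict(
        lambda: [0] * len(pair_ids)
    )
    for r in results:
        if r.call != "none" and r.pair_id in pair_pos:
            calls[r.gene_id][pair_pos[r.pair_id]] = 1 if r.call == "up" else -1
    out = []
    for gene in sorted(calls):
        vec = calls[gene]
        n_up = sum(v == 1 for v in vec)
        n_down = sum(v == -1 for v in vec)
        if n_up + n_down >= k_min:
            out.append(AggregatedDEG(gene, n_up + n_down, n_up, n_down, tuple(vec)))
    return out


def intersect_gene_list(
    aggregated: Sequence[AggregatedDEG], reference: Iterable[str]
) -> pd.DataFrame:
    """Annotate aggregated DEGs by exact (case-sensitive) membership in a
    reference gene list (e.g. a curated disease-gene set)."""
    ref = set(reference)
    rows = [
        {
            "gene_id": a.gene_id,
            "n_pairs_called": a.n_pairs_called,
            "n_up": a.n_up,
            "n_down": a.n_down,
            "in_reference": a.gene_id in ref,
        }
        for a in aggregated
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "n_pairs_called", "n_up", "n_down", "in_reference"]
    )


def cluster_degs(
    ternary: pd.DataFrame, method: str = "average"
) -> ClusterResult:
    """Hierarchical clustering of gene call vectors by Euclidean distance.

    Rows are genes, columns pairs, entries in {-1, 0, +1}.  Average linkage
    by default; SciPy's linkage breaks distance ties deterministically by
    input index, and the leaf order is emitted for heatmap rendering.
    """
    if len(ternary) < 2:
        return ClusterResult(np.empty((0, 4)), list(ternary.index), "euclidean",
                             method)
    Z = linkage(ternary.to_numpy(dtype=float), method=method, metric="euclidean")
    order = [str(ternary.index[i]) for i in leaves_list(Z)]
    return ClusterResult(Z, order, "euclidean", method)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts_tsv(path) -> ExpressionMatrix:
    """Read a counts table: columns gene_id, length, then one per sample."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    lengths = df.iloc[:, 0].astype(int)
    counts = df.iloc[:, 1:].astype(int)
    return ExpressionMatrix.from_counts(counts, lengths)


def read_pair_manifest(path) -> list[tuple[str, str, str]]:
    """Read (pair_id, case_id, control_id) rows from a TSV manifest."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"pair_id", "case_id", "control_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair manifest needs columns {sorted(required)}")
    return [tuple(r) for r in df[["pair_id", "case_id", "control_id"]].to_numpy()]
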