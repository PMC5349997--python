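"""Hypergeometric term enrichment with Bonferroni correction.

Used for GO-style (categories C/F/P) and KEGG-style (category "pathway")
term collections.  For a selected gene set of size n drawn from a universe
of N genes, a term with K members and k selected members gets the
hypergeometric upper-tail p = P(X >= k), Bonferroni-corrected by the number
of terms tested in its category (terms with at least one selected member).
GO terms are significant at corrected p <= 0.01, pathways at <= 0.05.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "TermCollection",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "enrich",
    "read_term_tsv",
    "GO_CATEGORIES",
]

GO_CATEGORIES = ("C", "F", "P")


@dataclass
class TermCollection:
    """term_id -> (name, category, member gene ids).

    Categories are GO namespaces C/F/P or "pathway"; members are
    de-duplicated on construction.
    """

    terms: dict[str, tuple[str, str, frozenset[str]]] = field(default_factory=dict)

    def add(self, term_id: str, name: str, category: str,
            members: Iterable[str]) -> None:
        prev = self.terms.get(term_id)
        mem = frozenset(members)
        if prev is not None:
            if prev[1] != category:
                raise ValueError(f"term {term_id}: conflicting categories")
            mem |= prev[2]
            name = name or prev[0]
        self.terms[term_id] = (name, category, mem)

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][2]

    def by_category(self, category: str) -> dict[str, frozenset[str]]:
        return {
            tid: mem for tid, (_, cat, mem) in self.terms.items() if cat == category
        }

    def categories(self) -> list[str]:
        return sorted({cat for _, cat, _ in self.terms.values()})


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    k: int  # selected genes in term
    K: int  # universe genes in term
    n: int  # selected genes in universe
    N: int  # universe size
    p: float
    p_corrected: float
    m_tests: int
    significant: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: term size, n: selection size, k: selected members
    of the term.  Arguments must be consistent (k <= min(K, n), K, n <= N).
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    selected: Iterable[str],
    terms: TermCollection,
    universe: Iterable[str],
    alpha_go: float = 0.01,
    alpha_kegg: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term with >= 1 selected member, per category.

    The Bonferroni multiplier m is the number of terms tested in the same
    category.  Selected genes outside the universe are dropped (their count
    is reflected in n).  GO categories (C/F/P) use ``alpha_go``; any other
    category uses ``alpha_kegg``.  Results are sorted by (category,
    corrected p, term_id).
    """
    universe_set = set(universe)
    selected_set = set(selected) & universe_set
    N = len(universe_set)
    n = len(selected_set)
    results: list[EnrichmentResult] = []
    for category in terms.categories():
        cat_terms = terms.by_category(category)
        tested = []
        for term_id, members in sorted(cat_terms.items()):
            members_u = members & universe_set
            k = len(members_u & selected_set)
            if k == 0:
                continue
            tested.append((term_id, len(members_u), k))
        m = len(tested)
        alpha = alpha_go if category in GO_CATEGORIES else alpha_kegg
        for term_id, K, k in tested:
            p = hypergeom_upper_tail(k, K, n, N)
            p_corr = min(1.0, m * p)
            results.append(
                EnrichmentResult(
                    term_id, terms.terms[term_id][0], category,
                    k, K, n, N, p, p_corr, m, p_corr <= alpha,
                )
            )
    results.sort(key=lambda r: (r.category, r.p_corrected, r.term_id))
    return results


def read_term_tsv(path) -> TermCollection:
    """Read a GAF-like flat mapping: term_id, category, gene_id[, term_name]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"term_id", "category", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"term mapping needs columns {sorted(required)}")
    tc = TermCollection()
    has_name = "term_name" in df.columns
    for (term_id, category), group in df.groupby(["term_id", "category"], sort=True):
        name = group["term_name"].iloc[0] if has_name else term_id
        tc.add(term_id, str(name), str(category), group["gene_id"].tolist())
    return tc


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name,
                "category": r.category, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p": r.p, "p_corrected": r.p_corrected, "m_tests": r.m_tests,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p",
                 "p_corrected", "m_tests", "significant"],
    )
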