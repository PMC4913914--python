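"""Gene-set over-representation and term-similarity grouping.

Over-representation of a query gene list in each annotation term is
scored two ways: the one-sided Fisher exact test (upper hypergeometric
tail, P(X >= k)) and its conservative EASE variant, which removes one
gene from the overlap before computing the tail — single-gene overlaps
can then never look significant.  Redundant enriched terms are grouped by
Cohen's kappa between their gene-membership vectors (the agreement score
functional-grouping tools use), joined greedily by single linkage above a
kappa threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fisher_term", "ease_term", "kappa_score", "group_terms",
           "enrich_table"]


def _check_margins(k: int, K: int, n: int, N: int) -> None:
    if min(k, K, n, N) < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N:
        raise ValueError(f"term size {K} and list size {n} must be <= background {N}")
    if k > min(K, n):
        raise ValueError(f"overlap {k} exceeds min(term={K}, list={n})")
    if k < K + n - N:
        raise ValueError("overlap below the hypergeometric support minimum")


def fisher_term(k: int, K: int, n: int, N: int) -> float:
    """One-sided Fisher exact p for a k-gene overlap.

    ``p = P(X >= k)`` with ``X ~ Hypergeometric(N, K, n)``: the chance a
    random n-gene list from an N-gene background hits the K-gene term at
    least k times.
    """
    _check_margins(k, K, n, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ease_term(k: int, K: int, n: int, N: int) -> float:
    """EASE score: Fisher exact with one overlap gene removed.

    ``p_ease = P(X >= k - 1)``; overlaps of 0 or 1 genes score 1, and
    ``p_ease >= p_fisher`` always (the tail only grows when its start
    moves down).
    """
    _check_margins(k, K, n, N)
    if k <= 1:
        return 1.0
    return float(stats.hypergeom.sf(k - 2, N, K, n))


def kappa_score(
    term_a: set[str], term_b: set[str], universe: set[str]
) -> float:
    """Cohen's kappa between two terms' membership vectors over a universe.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o (genes in
    both or neither term) and chance agreement p_e from the marginal
    membership rates.  Identical terms give 1; two disjoint terms that
    tile the universe give -1.  When both terms equal the whole universe
    (p_e = 1) kappa is defined as 1.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not term_a <= universe or not term_b <= universe:
        raise ValueError("terms must be subsets of the universe")
    N = len(universe)
    a = len(term_a)
    b = len(term_b)
    both = len(term_a & term_b)
    neither = N - len(term_a | term_b)
    p_o = (both + neither) / N
    p_e = (a * b + (N - a) * (N - b)) / (N * N)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def group_terms(
    terms: dict[str, set[str]],
    universe: set[str],
    p_ease: pd.Series | None = None,
    kappa_threshold: float = 0.4,
) -> list[list[str]]:
    """Greedy single-link grouping of terms by pairwise kappa.

    Terms whose kappa is at or above ``kappa_threshold`` are joined; under
    single linkage a chain A~B, B~C pulls A and C into one group even if
    they disagree directly.  Groups are seeded in ascending ``p_ease``
    order (ties lexicographic by term id), making the output order
    deterministic; every term lands in exactly one group.
    """
    ids = list(terms)
    if not ids:
        raise ValueError("no terms to group")
    if p_ease is None:
        p_ease = pd.Series(1.0, index=ids)
    order = sorted(ids, key=lambda t: (float(p_ease.get(t, 1.0)), t))
    assigned: dict[str, int] = {}
    groups: list[list[str]] = []
    for seed in order:
        if seed in assigned:
            continue
        gid = len(groups)
        group = [seed]
        assigned[seed] = gid
        frontier = [seed]
        while frontier:
            current = frontier.pop(0)
            for other in order:
                if other in assigned:
                    continue
                if kappa_score(terms[current], terms[other], universe) >= kappa_threshold:
                    assigned[other] = gid
                    group.append(other)
                    frontier.append(other)
        groups.append(group)
    return groups


def enrich_table(
    query: set[str],
    gene_sets: dict[str, set[str]],
    background: set[str] | int,
    descriptions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Score every term of a collection against a query gene list.

    ``background`` is either the explicit background gene set (query and
    terms are intersected with it) or an integer background size, in
    which case the query and term sets are taken at face value.  Returns
    one row per term: overlap ``k``, term size ``K``, list size ``n``,
    background ``N``, ``p_fisher``, ``p_ease`` and ``fold_enrichment``,
    sorted by ``p_ease``.
    """
    rows = []
    if isinstance(background, int):
        N = background
        q = set(query)
        clip = None
    else:
        clip = set(background)
        N = len(clip)
        q = set(query) & clip
    n = len(q)
    for term_id, genes in gene_sets.items():
        g = set(genes) if clip is None else set(genes) & clip
        K = len(g)
        k = len(q & g)
        if K == 0:
            continue
        fold = (k / n) / (K / N) if n and K else 0.0
        rows.append(
            {
                "term_id": term_id,
                "term_name": (descriptions or {}).get(term_id, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_fisher": fisher_term(k, K, n, N),
                "p_ease": ease_term(k, K, n, N),
                "fold_enrichment": fold,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["p_ease", "term_id"], kind="mergesort")
        out = out.set_index("term_id")
    return out
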