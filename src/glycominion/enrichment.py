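"""Term-enrichment statistics over glycan sets.

Given a query set of glycans (e.g. those co-localizing with one anatomical
region), a background universe, and the term → member index produced by
:func:`glycominion.classification.ontology_terms`, these functions ask which
class terms are over-represented in the query.  Four tests are provided, all
one-sided towards over-representation:

* Fisher's exact test — hypergeometric upper tail P(X >= k),
* the EASE score — Fisher with one observed hit removed, max(k-1, 0), a
  deliberately conservative variant popularised by DAVID,
* an exact binomial tail with success probability K/N,
* a two-sample Kolmogorov–Smirnov test on rank statistics (members vs
  non-members) for rank-based enrichment.

Multiple-testing adjustment is Benjamini–Hochberg by default (Bonferroni
selectable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "fisher_enrichment",
    "ease_enrichment",
    "binomial_enrichment",
    "ks_rank_enrichment",
    "adjust_pvalues",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentInput:
    """Query/universe/term-index bundle for one enrichment run.

    ``query`` may be a multiset; duplicates are collapsed to a set before
    testing (and logged).  ``ranks``, required only for the KS mode, maps
    every universe member to a rank statistic.
    """

    query: frozenset
    universe: frozenset
    term_index: Mapping[Hashable, frozenset]
    ranks: Mapping[Hashable, float] | None = None

    def __init__(self,
                 query: Iterable[Hashable],
                 universe: Iterable[Hashable],
                 term_index: Mapping[Hashable, Iterable[Hashable]],
                 ranks: Mapping[Hashable, float] | None = None) -> None:
        query_list = list(query)
        query_set = frozenset(query_list)
        if len(query_list) != len(query_set):
            logger.info("query contains %d duplicate identifiers; collapsed to a set",
                        len(query_list) - len(query_set))
        universe_set = frozenset(universe)
        if not universe_set:
            raise ValueError("universe must be non-empty")
        if not query_set:
            raise ValueError("query must be non-empty")
        if not query_set <= universe_set:
            missing = sorted(map(str, query_set - universe_set))[:5]
            raise ValueError(f"query is not a subset of the universe (e.g. {missing})")
        if not term_index:
            raise ValueError("term index must be non-empty")
        frozen_index = {}
        for term, members in term_index.items():
            member_set = frozenset(members)
            if not member_set <= universe_set:
                raise ValueError(f"term {term!r} has members outside the universe")
            frozen_index[term] = member_set
        if ranks is not None:
            missing_ranks = universe_set - set(ranks)
            if missing_ranks:
                raise ValueError("ranks must cover the universe; "
                                 f"{len(missing_ranks)} members are missing")
        object.__setattr__(self, "query", query_set)
        object.__setattr__(self, "universe", universe_set)
        object.__setattr__(self, "term_index", frozen_index)
        object.__setattr__(self, "ranks", dict(ranks) if ranks is not None else None)


@dataclass(frozen=True)
class EnrichmentResult:
    """Contingency counts, odds ratio and p/q-values for one term.

    k = query hits, n = query size, K = universe hits, N = universe size.
    Only the p-value of the test that produced the result is populated;
    ``untestable`` marks KS terms with no members or no non-members.
    """

    term: Hashable
    k: int
    n: int
    K: int
    N: int
    odds_ratio: float
    p_fisher: float | None = None
    p_ease: float | None = None
    p_binomial: float | None = None
    p_ks: float | None = None
    ks_statistic: float | None = None
    q_value: float | None = None
    untestable: bool = False

    @property
    def p_value(self) -> float | None:
        for p in (self.p_fisher, self.p_ease, self.p_binomial, self.p_ks):
            if p is not None:
                return p
        return None


def _table(inp: EnrichmentInput, term: Hashable) -> tuple[int, int, int, int]:
    members = inp.term_index[term]
    k = len(inp.query & members)
    n = len(inp.query)
    K = len(members)
    N = len(inp.universe)
    return k, n, K, N


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    # 2x2 table: [[k, n-k], [K-k, N-K-(n-k)]]; 0.5 continuity substitute
    # only when a margin zeroes a cell (display convention).
    a, b, c, d = k, n - k, K - k, N - K - (n - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _ordered_terms(inp: EnrichmentInput) -> list:
    return list(inp.term_index)


def _with_q(results: list[EnrichmentResult], method: str) -> list[EnrichmentResult]:
    testable = [r for r in results if not r.untestable]
    qs = adjust_pvalues([r.p_value for r in testable], method=method)
    q_by_term = {r.term: q for r, q in zip(testable, qs)}
    out = []
    for r in results:
        out.append(EnrichmentResult(
            term=r.term, k=r.k, n=r.n, K=r.K, N=r.N, odds_ratio=r.odds_ratio,
            p_fisher=r.p_fisher, p_ease=r.p_ease, p_binomial=r.p_binomial,
            p_ks=r.p_ks, ks_statistic=r.ks_statistic,
            q_value=q_by_term.get(r.term), untestable=r.untestable))
    return out


def fisher_enrichment(inp: EnrichmentInput, adjust: str = "bh") -> list[EnrichmentResult]:
    """One-sided Fisher exact (hypergeometric upper-tail) enrichment.

    For each term, p = P(X >= k) with X ~ Hypergeometric(N, K, n).
    """
    results = []
    for term in _ordered_terms(inp):
        k, n, K, N = _table(inp, term)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, n, K, N, _odds_ratio(k, n, K, N),
                                        p_fisher=min(p, 1.0)))
    return _with_q(results, adjust)


def ease_enrichment(inp: EnrichmentInput, adjust: str = "bh") -> list[EnrichmentResult]:
    """EASE-score enrichment: Fisher's tail with one hit removed.

    p = P(X >= max(k-1, 0)); always at least as large as the Fisher p for
    the same table, penalising single-hit terms.
    """
    results = []
    for term in _ordered_terms(inp):
        k, n, K, N = _table(inp, term)
        k_ease = max(k - 1, 0)
        p = float(stats.hypergeom.sf(k_ease - 1, N, K, n))
        results.append(EnrichmentResult(term, k, n, K, N, _odds_ratio(k, n, K, N),
                                        p_ease=min(p, 1.0)))
    return _with_q(results, adjust)


def binomial_enrichment(inp: EnrichmentInput, adjust: str = "bh") -> list[EnrichmentResult]:
    """Exact binomial-tail enrichment with success probability K/N.

    p = P(X >= k) for X ~ Binomial(n, K/N).  K/N = 0 with k > 0 gives p = 0
    without numerical failure (an impossible hit under the null).
    """
    results = []
    for term in _ordered_terms(inp):
        k, n, K, N = _table(inp, term)
        rate = K / N
        p = float(stats.binom.sf(k - 1, n, rate))
        results.append(EnrichmentResult(term, k, n, K, N, _odds_ratio(k, n, K, N),
                                        p_binomial=min(max(p, 0.0), 1.0)))
    return _with_q(results, adjust)


def ks_rank_enrichment(inp: EnrichmentInput, adjust: str = "bh",
                       mode: str = "two-sample") -> list[EnrichmentResult]:
    """Rank-based Kolmogorov–Smirnov enrichment.

    ``two-sample`` (default) compares the rank distribution of a term's
    members against non-members; ``one-sample`` compares members' normalised
    ranks against the uniform distribution on [0, 1].  P-values come from
    the asymptotic KS distribution.  Ties in the rank statistic are broken
    by a stable sort on the glycan identifier.  Terms whose members are the
    whole universe or empty are flagged ``untestable`` rather than raising.
    """
    if inp.ranks is None:
        raise ValueError("ks_rank_enrichment requires ranks")
    if mode not in ("two-sample", "one-sample"):
        raise ValueError(f"unknown KS mode: {mode!r}")
    # Stable identifier-keyed tie-break: rank order is (statistic, repr(id)).
    ordered_ids = sorted(inp.universe, key=lambda g: (inp.ranks[g], repr(g)))
    position = {g: i + 1 for i, g in enumerate(ordered_ids)}

    results = []
    for term in _ordered_terms(inp):
        k, n, K, N = _table(inp, term)
        members = inp.term_index[term]
        member_ranks = np.array([position[g] for g in members], dtype=float)
        other_ranks = np.array([position[g] for g in inp.universe - members], dtype=float)
        if member_ranks.size == 0 or other_ranks.size == 0:
            results.append(EnrichmentResult(term, k, n, K, N,
                                            _odds_ratio(k, n, K, N),
                                            p_ks=None, untestable=True))
            continue
        if mode == "two-sample":
            ks = stats.ks_2samp(member_ranks, other_ranks, method="asymp")
            d, p = float(ks.statistic), float(ks.pvalue)
        else:
            ks = stats.kstest(member_ranks / N, "uniform", method="asymp")
            d, p = float(ks.statistic), float(ks.pvalue)
        results.append(EnrichmentResult(term, k, n, K, N, _odds_ratio(k, n, K, N),
                                        p_ks=min(p, 1.0), ks_statistic=d))
    return _with_q(results, adjust)


def adjust_pvalues(pvalues: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment: Benjamini–Hochberg (``"bh"``, default)
    or Bonferroni (``"bonferroni"``).  An empty input yields an empty list;
    the BH step-up keeps q monotone in the p-value ranking."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    if any(p is None or not (0.0 <= p <= 1.0) for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method: {method!r}")
    _, q, _, _ = multipletests(pvalues, method=key)
    return [float(x) for x in q]
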