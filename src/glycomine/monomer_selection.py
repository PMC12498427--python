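"""Monomer-set selection: Fisher's-exact baseline and the probabilistic model.

A BGC is a binary gene-class presence vector ``b`` of length G.  A saccharide
is a binary vector ``(g, m)``: ``g_i`` marks gene class *i* as required by the
molecule's secondary monomers, ``m_j`` marks primary monomer *j* as present.

Baseline model: the upper-tail hypergeometric probability of the overlap
between the N annotated classes and the M required classes (gene-set
enrichment by Fisher's exact test).

Probabilistic model: assuming gene requirements are independent given the
BGC,

    P(saccharide | BGC) = prod_i P(g_i | b_i) * prod_j P(m_j)

with P(g=1|b=1)=alpha, P(g=0|b=1)=1-alpha, P(g=1|b=0)=beta,
P(g=0|b=0)=1-beta, and P(m=1)=gamma.  beta is the missing-gene rate: the
probability a gene class is used by the molecule although annotation did not
detect it in the BGC.  With co-occurrence counts a=#{g=1,b=1}, b=#{g=0,b=1},
c=#{g=1,b=0}, d=#{g=0,b=0} the likelihood is alpha^a (1-alpha)^b beta^c
(1-beta)^d gamma^e (1-gamma)^f and the maximum-likelihood estimates are the
closed forms alpha=a/(a+b), beta=c/(c+d), gamma=e/(e+f).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .knowledge_base import KnowledgeBase

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 gene-set enrichment table margins: total G, annotated N,
    required M, overlap O."""

    G: int
    N: int
    M: int
    O: int

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.G and 0 <= self.N <= self.G):
            raise ValueError(f"invalid margins {self}")
        if not 0 <= self.O <= min(self.M, self.N):
            raise ValueError(f"invalid overlap {self}")


@dataclass(frozen=True)
class TrainingCounts:
    """Aggregated label counts over all training (saccharide, BGC) pairs.

    ``a``..``d`` count (g_i, b_i) configurations over all pairs and gene
    classes; ``e``/``f`` count primary-monomer presence/absence.  ``n_pairs``
    is the number of training pairs (the training-set size, distinct from the
    contingency table's N).
    """

    a: int
    b: int
    c: int
    d: int
    e: int
    f: int
    n_pairs: int


@dataclass(frozen=True)
class ModelParams:
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SaccharideVector:
    g: tuple[int, ...]
    m: tuple[int, ...]


@dataclass(frozen=True)
class RankedMonomerSet:
    monomers: tuple[tuple[str, int], ...]  # (monomer id, multiplicity), sorted
    n_primary: int
    log_probability: float
    rank: int

    @property
    def monomer_ids(self) -> tuple[str, ...]:
        """Flattened id tuple with multiplicities expanded."""
        return tuple(
            mid for mid, count in self.monomers for _ in range(count)
        )


class DegenerateEstimateWarning(UserWarning):
    """An MLE hit the 0/1 boundary or had an empty denominator."""


# ---------------------------------------------------------------------------
# baseline model
# ---------------------------------------------------------------------------


def fisher_pvalue(counts: ContingencyCounts) -> float:
    """Upper-tail Fisher's exact P-value of the gene-set overlap.

    Computed exactly with integer binomials:
    ``P = sum_{i >= O} C(M, i) C(G-M, N-i) / C(G, N)``.
    """
    G, N, M, O = counts.G, counts.N, counts.M, counts.O
    denom = math.comb(G, N)
    total = 0
    for i in range(O, min(M, N) + 1):
        total += math.comb(M, i) * math.comb(G - M, N - i)
    return total / denom


# ---------------------------------------------------------------------------
# probabilistic model
# ---------------------------------------------------------------------------


def aggregate_counts(
    pairs: Sequence[tuple[SaccharideVector, Sequence[int]]]
) -> TrainingCounts:
    if not pairs:
        raise ValueError("at least one training pair required")
    G = len(pairs[0][0].g)
    K = len(pairs[0][0].m)
    a = b = c = d = e = f = 0
    for sacc, bgc in pairs:
        if len(sacc.g) != G or len(sacc.m) != K or len(bgc) != G:
            raise ValueError("inconsistent vector dimensions across training pairs")
        for gi, bi in zip(sacc.g, bgc):
            if bi:
                if gi:
                    a += 1
                else:
                    b += 1
            else:
                if gi:
                    c += 1
                else:
                    d += 1
        for mj in sacc.m:
            if mj:
                e += 1
            else:
                f += 1
    return TrainingCounts(a, b, c, d, e, f, len(pairs))


def params_from_counts(counts: TrainingCounts) -> ModelParams:
    """Closed-form MLE; boundary/degenerate estimates emit a warning."""

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(
                f"{name}: empty denominator; estimate undefined, returning 0",
                DegenerateEstimateWarning,
                stacklevel=3,
            )
            return 0.0
        value = num / den
        if value in (0.0, 1.0):
            warnings.warn(
                f"{name}: boundary estimate {value}", DegenerateEstimateWarning, stacklevel=3
            )
        return value

    alpha = ratio(counts.a, counts.a + counts.b, "alpha")
    beta = ratio(counts.c, counts.c + counts.d, "beta")
    gamma = ratio(counts.e, counts.e + counts.f, "gamma")
    return ModelParams(alpha=alpha, beta=beta, gamma=gamma)


def train_parameters(
    pairs: Sequence[tuple[SaccharideVector, Sequence[int]]]
) -> tuple[ModelParams, TrainingCounts]:
    """MLE of (alpha, beta, gamma) from (saccharide, BGC) training pairs."""
    counts = aggregate_counts(pairs)
    return params_from_counts(counts), counts


def log_probability(
    sacc: SaccharideVector, bgc: Sequence[int], params: ModelParams
) -> float:
    """log P(saccharide | BGC) under the factorized model.

    Returns ``-inf`` when a zero-probability configuration occurs (e.g.
    alpha = 1 and g_i = 0 with b_i = 1).
    """
    if len(sacc.g) != len(bgc):
        raise ValueError(f"dimension mismatch: g has {len(sacc.g)}, b has {len(bgc)}")
    alpha, beta, gamma = params.alpha, params.beta, params.gamma
    total = 0.0
    for gi, bi in zip(sacc.g, bgc):
        p = (alpha if gi else 1.0 - alpha) if bi else (beta if gi else 1.0 - beta)
        if p == 0.0:
            return NEG_INF
        total += math.log(p)
    for mj in sacc.m:
        p = gamma if mj else 1.0 - gamma
        if p == 0.0:
            return NEG_INF
        total += math.log(p)
    return total


# ---------------------------------------------------------------------------
# candidate-set enumeration and ranking
# ---------------------------------------------------------------------------


@dataclass
class EnumerationLimits:
    """Search-space limits for monomer-multiset enumeration.

    ``max_monomers`` covers the largest benchmark molecule (7 monomers);
    ``max_primary`` mirrors the up-to-two-primary-monomers policy;
    ``max_multiplicity`` allows the repeated units seen in glucose-rich
    oligosaccharides.
    """

    max_monomers: int = 7
    max_primary: int = 2
    max_multiplicity: int = 3
    top_n: int = 500
    #: admit secondary monomers with zero detected genes (scored through the
    #: 1-beta penalty) instead of requiring >= 1 supporting gene
    relax_eligibility: bool = False
    min_monomers: int = 1


def saccharide_vector_for_set(
    monomer_counts: Sequence[tuple[str, int]], kb: KnowledgeBase
) -> SaccharideVector:
    """Map a monomer multiset to its (g, m) vector.

    The g-vector is the union of the member secondary monomers' required
    gene classes (a gene shared by two monomers counts once); multiplicities
    do not change the vector.
    """
    gene_index = kb.gene_class_index()
    primary_index = kb.primary_index()
    g = [0] * len(gene_index)
    m = [0] * len(primary_index)
    for mid, _count in monomer_counts:
        mono = kb.monomers[mid]
        if mono.is_primary:
            m[primary_index[mid]] = 1
        else:
            for gid in mono.required_gene_classes:
                g[gene_index[gid]] = 1
    return SaccharideVector(g=tuple(g), m=tuple(m))


def eligible_monomers(
    bgc: Sequence[int], kb: KnowledgeBase, relax: bool = False
) -> tuple[list[str], list[str]]:
    """(secondary, primary) monomer ids admissible for a presence vector.

    A secondary monomer is eligible when at least one of its required gene
    classes is present; with ``relax`` every secondary monomer is admitted
    and unsupported ones pay the model's 1-beta penalty per required gene.
    """
    gene_index = kb.gene_class_index()
    secondary = []
    for mono in kb.secondary_monomers:
        supported = any(bgc[gene_index[gid]] for gid in mono.required_gene_classes)
        if supported or relax:
            secondary.append(mono.id)
    primary = [mono.id for mono in kb.primary_monomers]
    return secondary, primary


def _multisets(
    secondary: Sequence[str],
    primary: Sequence[str],
    limits: EnumerationLimits,
) -> Iterable[tuple[tuple[str, int], ...]]:
    """All monomer multisets within the limits, as sorted (id, count) tuples."""
    alphabet = sorted(secondary) + sorted(primary)
    primary_set = set(primary)
    max_mult = limits.max_multiplicity

    def rec(start: int, remaining: int, n_primary: int, acc: list[tuple[str, int]]):
        if acc and sum(c for _, c in acc) >= limits.min_monomers:
            yield tuple(sorted(acc))
        if remaining == 0 or start >= len(alphabet):
            return
        for idx in range(start, len(alphabet)):
            mid = alphabet[idx]
            is_primary = mid in primary_set
            for count in range(1, max_mult + 1):
                if count > remaining:
                    break
                added_primary = count if is_primary else 0
                if n_primary + added_primary > limits.max_primary:
                    break
                acc.append((mid, count))
                yield from rec(idx + 1, remaining - count, n_primary + added_primary, acc)
                acc.pop()

    # Deduplicate: rec yields each prefix as a complete multiset exactly once
    # because extension always moves to strictly later alphabet indices.
    yield from rec(0, limits.max_monomers, 0, [])


def enumerate_ranked_sets(
    bgc: Sequence[int],
    kb: KnowledgeBase,
    params: ModelParams,
    limits: EnumerationLimits | None = None,
) -> list[RankedMonomerSet]:
    """Enumerate, score, and rank candidate monomer multisets for a BGC.

    Sets are sorted by descending log-probability with ties broken by the
    lexicographic monomer-id tuple, then truncated to ``top_n``.  The result
    is a deterministic function of (bgc, params, limits).
    """
    limits = limits or EnumerationLimits()
    secondary, primary = eligible_monomers(bgc, kb, relax=limits.relax_eligibility)
    if not secondary and not primary:
        logger.warning("empty eligible monomer alphabet; no candidate sets")
        return []

    scored: list[tuple[float, tuple[str, ...], tuple[tuple[str, int], ...], int]] = []
    for multiset in _multisets(secondary, primary, limits):
        n_primary = sum(c for mid, c in multiset if kb.monomers[mid].is_primary)
        vector = saccharide_vector_for_set(multiset, kb)
        score = log_probability(vector, bgc, params)
        flat = tuple(mid for mid, c in multiset for _ in range(c))
        scored.append((score, flat, multiset, n_primary))

    scored.sort(key=lambda item: (-item[0], item[1]))
    return [
        RankedMonomerSet(
            monomers=multiset, n_primary=n_primary, log_probability=score, rank=i + 1
        )
        for i, (score, _flat, multiset, n_primary) in enumerate(scored[: limits.top_n])
    ]


def rank_sets_baseline(
    bgc: Sequence[int],
    kb: KnowledgeBase,
    limits: EnumerationLimits | None = None,
) -> list[RankedMonomerSet]:
    """Alternative ranking by the Fisher's-exact baseline (ascending P-value).

    Primary monomers carry no genes and hence do not influence the baseline
    score; the ``log_probability`` field stores log(P-value) for uniformity.
    """
    limits = limits or EnumerationLimits()
    secondary, primary = eligible_monomers(bgc, kb, relax=limits.relax_eligibility)
    G = len(bgc)
    N = int(sum(bgc))
    gene_index = kb.gene_class_index()
    scored = []
    for multiset in _multisets(secondary, primary, limits):
        required: set[str] = set()
        for mid, _c in multiset:
            required |= kb.monomers[mid].required_gene_classes
        M = len(required)
        O = sum(1 for gid in required if bgc[gene_index[gid]])
        p = fisher_pvalue(ContingencyCounts(G=G, N=N, M=M, O=O))
        n_primary = sum(c for mid, c in multiset if kb.monomers[mid].is_primary)
        flat = tuple(mid for mid, c in multiset for _ in range(c))
        scored.append((p, flat, multiset, n_primary))
    scored.sort(key=lambda item: (item[0], item[1]))
    return [
        RankedMonomerSet(
            monomers=multiset,
            n_primary=n_primary,
            log_probability=math.log(p) if p > 0 else NEG_INF,
            rank=i + 1,
        )
        for i, (p, _flat, multiset, n_primary) in enumerate(scored[: limits.top_n])
    ]
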