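"""Fisher baseline, probabilistic-model MLE and scoring, set enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycomine.monomer_selection import (
    ContingencyCounts,
    DegenerateEstimateWarning,
    EnumerationLimits,
    ModelParams,
    SaccharideVector,
    TrainingCounts,
    enumerate_ranked_sets,
    fisher_pvalue,
    log_probability,
    params_from_counts,
    rank_sets_baseline,
    saccharide_vector_for_set,
    train_parameters,
)
from glycomine.synthetic_fixtures import FixtureSpec, make_training_pairs


# ---------------------------------------------------------------- fisher


def _fisher_by_subset_enumeration(G, N, M, O):
    """Independent oracle: enumerate all C(G, N) annotated-gene subsets."""
    required = set(range(M))
    favorable = total = 0
    for subset in itertools.combinations(range(G), N):
        total += 1
        if len(required.intersection(subset)) >= O:
            favorable += 1
    return favorable / total


def test_fisher_trivial_tails():
    assert fisher_pvalue(ContingencyCounts(G=50, N=10, M=0, O=0)) == 1.0
    assert fisher_pvalue(ContingencyCounts(G=50, N=50, M=5, O=5)) == 1.0


def test_fisher_matches_subset_enumeration_oracle():
    value = fisher_pvalue(ContingencyCounts(G=10, N=4, M=5, O=3))
    assert value == pytest.approx(_fisher_by_subset_enumeration(10, 4, 5, 3), abs=1e-15)


def test_fisher_matches_independent_survival_function_on_grid():
    from scipy.stats import hypergeom

    for G in (5, 8, 12):
        for N in range(0, G + 1):
            for M in range(0, G + 1):
                for O in range(0, min(M, N) + 1):
                    ours = fisher_pvalue(ContingencyCounts(G=G, N=N, M=M, O=O))
                    ref = hypergeom.sf(O - 1, G, M, N)
                    assert ours == pytest.approx(ref, abs=1e-12), (G, N, M, O)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(2, 20), st.data())
def test_fisher_nonincreasing_in_overlap(G, data):
    N = data.draw(st.integers(0, G))
    M = data.draw(st.integers(0, G))
    values = [
        fisher_pvalue(ContingencyCounts(G=G, N=N, M=M, O=O))
        for O in range(0, min(M, N) + 1)
    ]
    assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))
    assert all(0.0 <= v <= 1.0 + 1e-15 for v in values)


def test_invalid_contingency_counts_raise():
    with pytest.raises(ValueError):
        ContingencyCounts(G=10, N=4, M=5, O=5)  # O > min(M, N)
    with pytest.raises(ValueError):
        ContingencyCounts(G=10, N=11, M=5, O=0)


# ---------------------------------------------------------------- MLE


def test_mle_closed_forms_on_hand_counts():
    params = params_from_counts(TrainingCounts(a=3, b=1, c=1, d=3, e=2, f=2, n_pairs=1))
    assert (params.alpha, params.beta, params.gamma) == (0.75, 0.25, 0.5)


def test_mle_boundary_flags_degenerate_estimate():
    pairs = [
        (SaccharideVector(g=(1, 1), m=(0,)), (1, 1)),
        (SaccharideVector(g=(1, 1), m=(0,)), (1, 1)),
    ]
    with pytest.warns(DegenerateEstimateWarning):
        params, counts = train_parameters(pairs)
    assert params.alpha == 1.0
    assert counts.c + counts.d == 0  # beta undefined


def test_training_counts_partition_invariant():
    spec = FixtureSpec(seed=3, G=20, K=4, n_pairs=50)
    pairs = make_training_pairs(spec)
    _params, counts = train_parameters(pairs)
    assert counts.a + counts.b + counts.c + counts.d == counts.n_pairs * spec.G
    assert counts.e + counts.f == counts.n_pairs * spec.K


@pytest.mark.parametrize("n_pairs,tol", [(50, 0.15), (500, 0.05)])
def test_parameter_recovery_from_simulated_pairs(n_pairs, tol):
    """Estimates converge on the generating (alpha, beta, gamma)."""
    spec = FixtureSpec(seed=42, G=50, K=6, alpha=0.9, beta=0.05, gamma=0.3, n_pairs=n_pairs)
    params, _counts = train_parameters(make_training_pairs(spec))
    assert params.alpha == pytest.approx(0.9, abs=tol)
    assert params.beta == pytest.approx(0.05, abs=tol)
    assert params.gamma == pytest.approx(0.3, abs=tol)


# ---------------------------------------------------------------- scoring


def test_log_probability_closed_form_all_zero(params):
    G, K = 5, 3
    sacc = SaccharideVector(g=(0,) * G, m=(0,) * K)
    value = log_probability(sacc, (0,) * G, params)
    expected = G * math.log(1 - params.beta) + K * math.log(1 - params.gamma)
    assert value == pytest.approx(expected, rel=1e-12)


def test_log_probability_flip_identity(params):
    """Flipping one g_i from 0 to 1 where b_i = 1 changes the score by
    log(alpha / (1 - alpha))."""
    base = SaccharideVector(g=(0, 0, 0), m=())
    flipped = SaccharideVector(g=(1, 0, 0), m=())
    bgc = (1, 0, 0)
    delta = log_probability(flipped, bgc, params) - log_probability(base, bgc, params)
    assert delta == pytest.approx(math.log(params.alpha / (1 - params.alpha)), rel=1e-12)


@pytest.mark.parametrize("bgc", [(0, 0, 0), (1, 0, 1), (1, 1, 1)])
def test_likelihood_normalizes_over_saccharide_space(params, bgc):
    """Sum of exp(log P) over all 2^(G+K) saccharide vectors equals 1."""
    G, K = 3, 2
    total = 0.0
    for g in itertools.product((0, 1), repeat=G):
        for m in itertools.product((0, 1), repeat=K):
            total += math.exp(log_probability(SaccharideVector(g=g, m=m), bgc, params))
    assert total == pytest.approx(1.0, abs=1e-10)


def test_log_probability_zero_probability_sentinel():
    degenerate = ModelParams(alpha=1.0, beta=0.05, gamma=0.3)
    sacc = SaccharideVector(g=(0,), m=())
    assert log_probability(sacc, (1,), degenerate) == float("-inf")


def test_dimension_mismatch_raises(params):
    with pytest.raises(ValueError):
        log_probability(SaccharideVector(g=(0, 1), m=()), (0,), params)


# ---------------------------------------------------------------- enumeration


def _brute_force_multiset_count(n_secondary, n_primary, max_monomers, max_primary, max_mult):
    """Independent multiset counter over explicit id tuples."""
    ids = [("s", i) for i in range(n_secondary)] + [("p", i) for i in range(n_primary)]
    seen = set()
    for size in range(1, max_monomers + 1):
        for combo in itertools.combinations_with_replacement(ids, size):
            counts = {x: combo.count(x) for x in combo}
            if any(c > max_mult for c in counts.values()):
                continue
            if sum(c for (kind, _), c in counts.items() if kind == "p") > max_primary:
                continue
            seen.add(combo)
    return len(seen)


def test_enumeration_count_matches_brute_force(toy_kb, params):
    limits = EnumerationLimits(max_monomers=3, max_primary=2, max_multiplicity=1, top_n=10**9)
    bgc = tuple(1 for _ in toy_kb.gene_class_ids)  # everything eligible
    ranked = enumerate_ranked_sets(bgc, toy_kb, params, limits)
    expected = _brute_force_multiset_count(
        n_secondary=len(toy_kb.secondary_monomers),
        n_primary=len(toy_kb.primary_monomers),
        max_monomers=3,
        max_primary=2,
        max_mult=1,
    )
    assert len(ranked) == expected


def test_zero_presence_vector_admits_only_primary_sets(toy_kb, params):
    bgc = tuple(0 for _ in toy_kb.gene_class_ids)
    ranked = enumerate_ranked_sets(bgc, toy_kb, params, EnumerationLimits(top_n=10**9))
    assert ranked
    for rset in ranked:
        assert all(toy_kb.monomers[mid].is_primary for mid, _c in rset.monomers)


def test_relaxation_admits_unsupported_monomers(toy_kb, params):
    bgc = tuple(0 for _ in toy_kb.gene_class_ids)
    limits = EnumerationLimits(top_n=10**9, relax_eligibility=True)
    ranked = enumerate_ranked_sets(bgc, toy_kb, params, limits)
    assert any(
        not toy_kb.monomers[mid].is_primary for rset in ranked for mid, _c in rset.monomers
    )


def test_gene_supported_set_outranks_unsupported(toy_kb, params):
    """With alpha > beta, a fully supported monomer outranks an unsupported
    one of the same size (the unsupported genes pay the beta penalty)."""
    idx = toy_kb.gene_class_index()
    supported = toy_kb.monomers["t_aminohexose"]
    unsupported = toy_kb.monomers["t_aldopentose"]
    bgc = [0] * len(idx)
    for gid in supported.required_gene_classes:
        bgc[idx[gid]] = 1
    limits = EnumerationLimits(max_monomers=1, top_n=10**9, relax_eligibility=True)
    ranked = enumerate_ranked_sets(tuple(bgc), toy_kb, params, limits)
    position = {rset.monomers[0][0]: rset.rank for rset in ranked if len(rset.monomers) == 1}
    assert position[supported.id] < position[unsupported.id]


def test_ranking_is_deterministic(toy_kb, params):
    bgc = tuple(1 for _ in toy_kb.gene_class_ids)
    limits = EnumerationLimits(max_monomers=3, top_n=50)
    first = enumerate_ranked_sets(bgc, toy_kb, params, limits)
    second = enumerate_ranked_sets(bgc, toy_kb, params, limits)
    assert first == second
    assert [r.rank for r in first] == list(range(1, len(first) + 1))
    scores = [r.log_probability for r in first]
    assert scores == sorted(scores, reverse=True)


def test_saccharide_vector_union_semantics(toy_kb):
    """A gene class shared by two monomers counts once in the g-vector."""
    vec_pair = saccharide_vector_for_set(
        [("t_aminohexose", 1), ("t_deoxyhexose", 1)], toy_kb
    )
    union = set(toy_kb.monomers["t_aminohexose"].required_gene_classes) | set(
        toy_kb.monomers["t_deoxyhexose"].required_gene_classes
    )
    assert sum(vec_pair.g) == len(union)
    vec_multi = saccharide_vector_for_set([("t_aminohexose", 3)], toy_kb)
    vec_single = saccharide_vector_for_set([("t_aminohexose", 1)], toy_kb)
    assert vec_multi == vec_single  # multiplicity does not change the vector


def test_baseline_ranking_prefers_enriched_sets(toy_kb):
    idx = toy_kb.gene_class_index()
    bgc = [0] * len(idx)
    for gid in toy_kb.monomers["t_aminohexose"].required_gene_classes:
        bgc[idx[gid]] = 1
    ranked = rank_sets_baseline(tuple(bgc), toy_kb, EnumerationLimits(max_monomers=1, top_n=10))
    assert ranked[0].monomers[0][0] == "t_aminohexose"
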