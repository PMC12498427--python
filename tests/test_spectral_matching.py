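"""Fragmentation, shared-peak scoring, variable search, decoy p-values."""

import itertools

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from glycomine.backbone_assembly import assemble_backbones
from glycomine.spectral_matching import (
    ADDUCTS,
    ExperimentalSpectrum,
    SearchConfig,
    bridge_bonds,
    empirical_pvalue,
    fragment,
    score_match,
    search,
    variable_score,
)

GLUCOSE = "OCC1OC(O)C(O)C(O)C1O"
PROTON = ADDUCTS["[M+H]+"]


@pytest.fixture(scope="module")
def trisaccharide(toy_kb):
    return assemble_backbones(["t_aminohexose", "t_glucose", "t_aldopentose"], toy_kb)[0]


def _self_spectrum(theo, adduct="[M+H]+"):
    peaks = tuple(sorted((f.mass + ADDUCTS[adduct], 100.0) for f in theo.fragments))
    return ExperimentalSpectrum("self", theo.intact_mass + ADDUCTS[adduct], 1, peaks)


# ---------------------------------------------------------------- fragment


def test_single_monomer_has_no_bridges_and_one_fragment():
    theo = fragment(GLUCOSE)
    assert len(theo.fragments) == 1
    assert theo.fragments[0].mass == pytest.approx(theo.intact_mass, abs=1e-9)
    assert bridge_bonds(Chem.MolFromSmiles(GLUCOSE)) == []


def test_fragments_match_bond_subset_oracle(trisaccharide):
    """Fragment multiset equals exhaustive enumeration over <=2-bridge
    subsets, computed independently with networkx components."""
    mol = Chem.MolFromSmiles(trisaccharide.smiles)
    bridges = bridge_bonds(mol)
    assert len(bridges) >= 2

    graph = nx.Graph()
    for bond in mol.GetBonds():
        graph.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), idx=bond.GetIdx())
    masses = {
        a.GetIdx(): Chem.GetPeriodicTable().GetMostCommonIsotopeMass(a.GetAtomicNum())
        + a.GetTotalNumHs() * 1.0078250319
        for a in mol.GetAtoms()
    }
    expected = set()
    for k in (0, 1, 2):
        for subset in itertools.combinations(bridges, k):
            sub = nx.Graph(
                (u, v) for u, v, d in graph.edges(data=True) if d["idx"] not in subset
            )
            sub.add_nodes_from(graph.nodes)
            for comp in nx.connected_components(sub):
                expected.add(round(sum(masses[i] for i in comp), 5))
    theo = fragment(trisaccharide.smiles, max_cuts=2)
    assert {round(f.mass, 5) for f in theo.fragments} == expected


def test_fragment_containment_properties(trisaccharide):
    theo = fragment(trisaccharide.smiles, max_cuts=2)
    assert max(f.mass for f in theo.fragments) == pytest.approx(theo.intact_mass, abs=1e-9)
    assert all(f.mass <= theo.intact_mass + 1e-9 for f in theo.fragments)


# ---------------------------------------------------------------- scoring


def test_self_match_scores_every_peak(trisaccharide):
    theo = fragment(trisaccharide.smiles)
    exp = _self_spectrum(theo)
    assert score_match(theo, exp) == len(exp.peaks)


def test_distant_peaks_score_zero(trisaccharide):
    theo = fragment(trisaccharide.smiles)
    peaks = tuple((f.mass + PROTON + 5.0, 10.0) for f in theo.fragments)
    exp = ExperimentalSpectrum("far", theo.intact_mass + PROTON, 1, tuple(sorted(peaks)))
    assert score_match(theo, exp, tol=0.01) == 0


def test_planted_plus_random_peaks_score_exactly_planted(trisaccharide):
    rng = np.random.default_rng(13)
    theo = fragment(trisaccharide.smiles, max_cuts=2)
    frag_mzs = sorted(f.mass + PROTON for f in theo.fragments)
    planted = frag_mzs[:6]
    noise = []
    while len(noise) < 4:
        mz = float(rng.uniform(60.0, 700.0))
        if min(abs(mz - f) for f in frag_mzs) > 0.05:
            noise.append(mz)
    peaks = tuple(sorted([(mz, 99.0) for mz in planted] + [(mz, 5.0) for mz in noise]))
    exp = ExperimentalSpectrum("planted", theo.intact_mass + PROTON, 1, peaks)
    assert score_match(theo, exp, tol=0.01) == 6


def test_intensity_weighted_mode_returns_matched_fraction(trisaccharide):
    theo = fragment(trisaccharide.smiles, max_cuts=2)
    frag_mzs = sorted(f.mass + PROTON for f in theo.fragments)
    peaks = ((frag_mzs[0], 75.0), (frag_mzs[1], 20.0), (frag_mzs[-1] + 50.0, 5.0))
    exp = ExperimentalSpectrum("w", theo.intact_mass + PROTON, 1, tuple(sorted(peaks)))
    weighted = score_match(theo, exp, intensity_weighted=True)
    assert weighted == pytest.approx(0.95, abs=1e-9)
    assert score_match(theo, exp) == 2


def test_unknown_adduct_raises(trisaccharide):
    theo = fragment(trisaccharide.smiles)
    with pytest.raises(ValueError):
        score_match(theo, _self_spectrum(theo), adduct="[M+Xx]+")


# ---------------------------------------------------------------- variable


def test_variable_recovers_terminal_monomer_loss(toy_kb, trisaccharide):
    """A spectrum of the structure minus a terminal monomer is recovered at a
    shift of -(monomer mass - water) and scores like the truncation's
    self-match."""
    truncated = assemble_backbones(["t_aminohexose", "t_glucose"], toy_kb)[0]
    theo_full = fragment(trisaccharide.smiles, max_cuts=2)
    theo_trunc = fragment(truncated.smiles, max_cuts=2)
    exp = _self_spectrum(theo_trunc)
    score, shift = variable_score(theo_full, exp)
    expected_shift = theo_trunc.intact_mass - theo_full.intact_mass
    assert shift == pytest.approx(expected_shift, abs=1e-6)
    assert shift == pytest.approx(
        -(toy_kb.monomers["t_aldopentose"].monoisotopic_mass - 18.010565), abs=1e-4
    )
    assert score > score_match(theo_full, exp)


def test_zero_shift_bounds_degenerate_to_standard(trisaccharide):
    theo = fragment(trisaccharide.smiles)
    exp = _self_spectrum(theo)
    score, shift = variable_score(theo, exp, shift_bounds=(0.0, 0.0))
    assert shift == 0.0
    assert score == score_match(theo, exp)


def test_variable_never_below_standard(trisaccharide):
    rng = np.random.default_rng(5)
    theo = fragment(trisaccharide.smiles, max_cuts=2)
    for i in range(100):
        n = int(rng.integers(3, 12))
        peaks = tuple(sorted((float(rng.uniform(60, 700)), 10.0) for _ in range(n)))
        exp = ExperimentalSpectrum(f"r{i}", float(rng.uniform(200, 700)), 1, peaks)
        var, _shift = variable_score(theo, exp)
        assert var >= score_match(theo, exp)


# ---------------------------------------------------------------- p-values


def test_zero_score_gives_pvalue_one(trisaccharide):
    theo = fragment(trisaccharide.smiles)
    exp = ExperimentalSpectrum("empty-ish", 500.0, 1, ((700.0, 1.0),))
    p = empirical_pvalue(0, theo, exp, n_decoys=99, rng=np.random.default_rng(0))
    assert p == 1.0


def test_self_match_is_significant(trisaccharide):
    theo = fragment(trisaccharide.smiles, max_cuts=2)
    exp = _self_spectrum(theo)
    score = score_match(theo, exp)
    p = empirical_pvalue(score, theo, exp, n_decoys=999, rng=np.random.default_rng(2))
    assert p <= 1e-3


def test_decoy_pvalues_are_valid_and_approximately_uniform():
    """Under the decoy null the p-values are conservative -- P(p <= t) stays
    below t plus the 1/(n_decoys+1) discreteness offset -- and approximately
    uniform (KS) when the score distribution is dense.  The observed
    candidate is drawn from the same process as the decoys, so its rank is
    exchangeable."""
    from scipy.stats import kstest

    from glycomine.spectral_matching import Fragment, TheoreticalSpectrum

    rng = np.random.default_rng(8)
    n_decoys = 99
    pvalues = []
    for i in range(200):
        masses = np.sort(rng.uniform(100, 400, size=25))
        theo = TheoreticalSpectrum(
            "null-cand", 400.0, tuple(Fragment(float(m), 0, "") for m in masses)
        )
        peaks = tuple(sorted((float(rng.uniform(100, 400)), 10.0) for _ in range(25)))
        exp = ExperimentalSpectrum(f"null{i}", 360.0, 1, peaks)
        score = score_match(theo, exp, tol=3.0)
        pvalues.append(
            empirical_pvalue(score, theo, exp, tol=3.0, n_decoys=n_decoys,
                             rng=np.random.default_rng(1000 + i))
        )
    pvalues = np.array(pvalues)
    assert pvalues.min() > 0.0 and pvalues.max() <= 1.0
    offset = 1.0 / (n_decoys + 1)
    for t in (0.05, 0.1, 0.2, 0.5):
        # validity with a 3-sigma sampling allowance on 200 draws
        slack = 3 * np.sqrt(t * (1 - t) / len(pvalues))
        assert (pvalues <= t).mean() <= t + offset + slack, t
    stat, _ = kstest(pvalues, "uniform")
    assert stat <= 0.2


def test_too_few_decoys_rejected(trisaccharide):
    theo = fragment(trisaccharide.smiles)
    with pytest.raises(ValueError):
        empirical_pvalue(1, theo, _self_spectrum(theo), n_decoys=10)


# ---------------------------------------------------------------- search


def test_search_planted_candidate_ranks_first(toy_kb, trisaccharide):
    """Noise-free planted spectrum among decoy candidates: the planted
    structure is the top hit at p <= 1e-3 with 999 decoys."""
    theo = fragment(trisaccharide.smiles, max_cuts=2)
    exp = _self_spectrum(theo)
    rng = np.random.default_rng(21)
    candidates = [("planted", trisaccharide.smiles, theo.intact_mass)]
    # decoys at the same precursor mass so they pass the filter
    for i in range(55):
        n_frag = 8
        candidates.append((f"decoy{i}", GLUCOSE, theo.intact_mass))
    results = search(candidates, [exp], SearchConfig(n_decoys=999, seed=4, report_all=True))
    assert results
    assert results[0].candidate_id == "planted"
    assert results[0].p_value <= 1e-3
    best_by_id = {}
    for r in results:
        best_by_id.setdefault(r.candidate_id, r)
    for cid, r in best_by_id.items():
        if cid != "planted":
            assert r.score <= results[0].score


def test_search_empty_spectra_yields_empty_table(trisaccharide):
    results = search([("c", trisaccharide.smiles, 500.0)], [], SearchConfig())
    assert results == []


def test_search_precursor_filter_skips_all(trisaccharide):
    theo = fragment(trisaccharide.smiles)
    exp = ExperimentalSpectrum("off", theo.intact_mass + PROTON + 300.0, 1, ((100.0, 1.0),))
    results = search(
        [("c", trisaccharide.smiles, theo.intact_mass)], [exp],
        SearchConfig(report_all=True),
    )
    assert results == []


def test_search_is_deterministic(trisaccharide):
    theo = fragment(trisaccharide.smiles, max_cuts=2)
    exp = _self_spectrum(theo)
    config = SearchConfig(n_decoys=199, seed=9, report_all=True)
    candidates = [("planted", trisaccharide.smiles, theo.intact_mass)]
    assert search(candidates, [exp], config) == search(candidates, [exp], config)
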