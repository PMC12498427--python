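"""Motif matching, command replay, and mature-candidate enumeration."""

import itertools

import pytest
from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt

from glycomine.knowledge_base import ModificationRule, parse_program
from glycomine.modification_engine import (
    RuleApplicationError,
    apply_rule,
    enumerate_mature,
    enumerate_mature_for_bgc,
    match_motif,
    replay_commands,
)

GLUCOSE = "OCC1OC(O)C(O)C(O)C1O"


def _rule(rid, motif, program, delta, enzymes=("gcT5",)):
    return ModificationRule(
        id=rid,
        name=rid,
        enzyme_gene_classes=frozenset(enzymes),
        motif_smiles=motif,
        commands=parse_program(program),
        mass_delta=delta,
    )


# ---------------------------------------------------------------- matching


def test_hydroxyl_motif_sites_match_subgraph_oracle():
    """One site per distinct C-O(H) pair, verified against an exhaustive
    neighbor scan."""
    mol = Chem.MolFromSmiles(GLUCOSE)
    sites = match_motif(mol, "CO")
    oracle = {
        frozenset((n.GetIdx(), atom.GetIdx()))
        for atom in mol.GetAtoms()
        if atom.GetSymbol() == "O"
        for n in atom.GetNeighbors()
        if n.GetSymbol() == "C"
    }
    assert {frozenset(s) for s in sites} == oracle


def test_absent_motif_yields_no_sites():
    mol = Chem.MolFromSmiles(GLUCOSE)
    assert match_motif(mol, "CN") == []
    assert match_motif(mol, "C(=O)O") == []


def test_whole_structure_motif_collapses_to_one_site():
    mol = Chem.MolFromSmiles("OCCO")  # symmetric: automorphic images collapse
    sites = match_motif(mol, "OCCO")
    assert len(sites) == 1


def test_unparseable_motif_raises():
    with pytest.raises(ValueError):
        match_motif(Chem.MolFromSmiles(GLUCOSE), "C1CC(")


# ---------------------------------------------------------------- replay


def test_aminotransferase_program_turns_carbonyl_into_amine():
    """disconnect C=O; remove O; add N,H,H; connect -> amine where the
    carbonyl oxygen was."""
    rule = _rule(
        "amino", "C=O",
        "disconnect 1 2;remove 2;add 3 N;add 4 H;add 5 H;connect 3 4 1;connect 3 5 1;connect 1 3 1",
        1.0316,
    )
    ketone = Chem.MolFromSmiles("CC(C)=O")
    sites = match_motif(ketone, rule.motif_smiles)
    product = apply_rule(ketone, rule, sites[0])
    assert Chem.MolToSmiles(product) == "CC(C)N"


def test_dehydratase_connect_creates_double_bond():
    """'connect 1 4 2' installs a bond of order 2 and the net change is -H2O."""
    rule = _rule("dehyd", "C(CO)O", "disconnect 2 3;remove 3;connect 1 4 2", -18.0106)
    diol = Chem.MolFromSmiles("CC(O)CO")  # propylene glycol: one valid site
    products = []
    for site in match_motif(diol, rule.motif_smiles):
        try:
            products.append(apply_rule(diol, rule, site))
        except RuleApplicationError:
            continue
    assert products
    found_double = False
    for product in products:
        assert ExactMolWt(product) - ExactMolWt(diol) == pytest.approx(-18.0106, abs=1e-3)
        for bond in product.GetBonds():
            if bond.GetBondType() == Chem.BondType.DOUBLE:
                found_double = True
    assert found_double


def test_empty_program_is_identity():
    rule = _rule("ident", "CO", "-", 0.0)
    mol = Chem.MolFromSmiles(GLUCOSE)
    product = apply_rule(mol, rule, match_motif(mol, "CO")[0])
    assert Chem.MolToSmiles(product) == Chem.MolToSmiles(mol)


def test_command_referencing_missing_atom_raises():
    rule = _rule("bad", "CO", "connect 1 9 1", 0.0)
    mol = Chem.MolFromSmiles(GLUCOSE)
    with pytest.raises(RuleApplicationError):
        apply_rule(mol, rule, match_motif(mol, "CO")[0])


def test_mass_delta_mismatch_site_is_rejected():
    """A site where the replay produces a different elemental change than the
    rule's stored delta (here: the motif O maps onto a ring ether) raises,
    so enumeration skips it."""
    rule = _rule("deoxy", "CO", "disconnect 1 2;remove 2", -15.9949)
    mol = Chem.MolFromSmiles(GLUCOSE)
    outcomes = {"ok": 0, "skip": 0}
    for site in match_motif(mol, "CO"):
        try:
            apply_rule(mol, rule, site)
            outcomes["ok"] += 1
        except RuleApplicationError:
            outcomes["skip"] += 1
    assert outcomes["ok"] == 5  # five genuine hydroxyls
    assert outcomes["skip"] > 0  # ring/ether embeddings rejected


def test_replay_detects_valence_violation():
    rule = _rule("overbond", "CO", "connect 1 2 3", 0.0)
    mol = Chem.MolFromSmiles(GLUCOSE)
    with pytest.raises(RuleApplicationError):
        replay_commands(mol, rule.commands, dict(enumerate(match_motif(mol, "CO")[0], start=1)))


# ---------------------------------------------------------------- enumeration


def test_no_active_rules_returns_backbone_only():
    result = enumerate_mature(GLUCOSE, [])
    assert len(result) == 1
    assert result[0].applied_rules == ()
    assert result[0].smiles == Chem.MolToSmiles(Chem.MolFromSmiles(GLUCOSE))


def test_two_site_rule_depth_two_matches_powerset_oracle():
    """One rule, two symmetry-distinct sites, depth 2: candidates are the
    powerset {none, site1, site2, both} minus canonical duplicates."""
    substrate = "OCCCO"  # symmetric diol: two O-methylation sites
    rule = _rule("ometh", "CO", "add 3 C;connect 2 3 1", 14.0157)
    result = enumerate_mature(substrate, [rule], max_depth=2)
    smiles = {c.smiles for c in result}
    base = Chem.CanonSmiles(substrate)
    one = Chem.CanonSmiles("COCCCO")
    both = Chem.CanonSmiles("COCCCOC")
    # methylated ethers cannot accept a second methyl (valence-rejected), so
    # the reachable set is exactly the powerset modulo symmetry duplicates
    assert smiles == {base, one, both}
    by_smiles = {c.smiles: c for c in result}
    assert len(by_smiles[both].applied_rules) == 2


def test_inactive_rule_is_never_applied(toy_kb):
    result = enumerate_mature_for_bgc(GLUCOSE, toy_kb, present_gene_classes=["gcT1"])
    assert len(result) == 1  # toy rules need gcT5 (and gcT6): backbone only


def test_multi_enzyme_rule_needs_all_classes(toy_kb):
    partial = enumerate_mature_for_bgc(GLUCOSE, toy_kb, ["gcT5"])
    full = enumerate_mature_for_bgc(GLUCOSE, toy_kb, ["gcT5", "gcT6"])
    applied_partial = {rid for c in partial for rid, _s in c.applied_rules}
    applied_full = {rid for c in full for rid, _s in c.applied_rules}
    assert "tmod_deoxy" not in applied_partial
    assert "tmod_deoxy" in applied_full


def test_mass_bookkeeping_for_all_mature_candidates(real_kb):
    rules = [real_kb.modifications[r] for r in ("mod01", "mod05", "mod11")]
    substrate = "NC1C(O)C(O)C(CO)OC1O"
    base_mass = ExactMolWt(Chem.MolFromSmiles(substrate))
    deltas = {r.id: r.mass_delta for r in rules}
    result = enumerate_mature(substrate, rules, max_depth=2, max_candidates=300)
    assert len(result) > 1
    for cand in result:
        expected = base_mass + sum(deltas[rid] for rid, _s in cand.applied_rules)
        assert cand.monoisotopic_mass == pytest.approx(expected, abs=1e-4)


def test_enumeration_invariant_to_rule_order(real_kb):
    rules = [real_kb.modifications[r] for r in ("mod01", "mod02", "mod05")]
    substrate = "NC1C(O)C(O)C(CO)OC1O"
    baseline = {c.smiles for c in enumerate_mature(substrate, rules, max_depth=2)}
    for perm in itertools.permutations(rules):
        assert {c.smiles for c in enumerate_mature(substrate, list(perm), max_depth=2)} == baseline


def test_round_trip_rule_and_inverse_restore_structure(real_kb):
    """Oxidation to ketone then ketoreduction restores the original graph."""
    oxidize = real_kb.modifications["mod06"]
    reduce_ = real_kb.modifications["mod18"]
    substrate = Chem.MolFromSmiles("CC(O)CC")
    original = Chem.MolToSmiles(substrate)
    oxidized = None
    for site in match_motif(substrate, oxidize.motif_smiles):
        try:
            oxidized = apply_rule(substrate, oxidize, site)
            break
        except RuleApplicationError:
            continue
    assert oxidized is not None
    restored = set()
    for site in match_motif(oxidized, reduce_.motif_smiles):
        try:
            restored.add(Chem.MolToSmiles(apply_rule(oxidized, reduce_, site)))
        except RuleApplicationError:
            continue
    assert original in restored


def test_cap_truncation(real_kb):
    rules = [real_kb.modifications["mod01"]]
    result = enumerate_mature(GLUCOSE, rules, max_depth=3, max_candidates=4)
    assert len(result) == 4
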