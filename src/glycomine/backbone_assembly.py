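"""Combinatorial assembly of monomer multisets into linear saccharide backbones.

A candidate backbone is a linear chain of monomers joined by the knowledge
base's bond-formation rules.  Every ordering of the multiset is enumerated
(deduplicated under identical-monomer symmetry), and at every junction every
compatible (bond rule, donor side, donor group, acceptor group) choice is
tried.  Reactive-group accounting follows saccharide chain chemistry: the two
terminal monomers each consume exactly one reactive group, internal monomers
consume two, and no group is consumed twice.  Branching is not enumerated.

Bond chemistry on the molecular graph:

* glycosylation / ribosylation -- the donor's activated anomeric hydroxyl
  (the placeholder for its NDP activating group) leaves and the anomeric
  carbon bonds to the acceptor hydroxyl oxygen (net loss H2O);
* dehydration -- a donor ketone condenses with an acceptor amine to an imine
  (net loss H2O);
* amidation -- a donor carboxyl condenses with an acceptor amine to an amide
  (net loss H2O).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt

from .knowledge_base import BondRule, KnowledgeBase, MASS_TOL, MonomerRecord

logger = logging.getLogger(__name__)

_TAG = "_gm_assembly_tag"


@dataclass(frozen=True)
class BondAssignment:
    """One junction of a backbone: which rule consumed which groups.

    ``donor_side`` is ``"left"`` when the earlier monomer of the adjacent
    pair donates; group indices are positions into each monomer's
    ``reactive_groups`` tuple.
    """

    rule_id: str
    donor_side: str
    donor_group: int
    acceptor_group: int


@dataclass(frozen=True)
class BackboneCandidate:
    monomer_order: tuple[str, ...]
    bond_assignments: tuple[BondAssignment, ...]
    smiles: str
    monoisotopic_mass: float


def canonical_smiles(structure: str | Chem.Mol) -> str:
    """Stereochemistry-free canonical SMILES; equal for isomorphic graphs."""
    mol = Chem.MolFromSmiles(structure) if isinstance(structure, str) else Chem.Mol(structure)
    if mol is None:
        raise ValueError(f"unparseable structure {structure!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# low-level bond formation
# ---------------------------------------------------------------------------


def _tagged_atom(mol: Chem.Mol, tag: int) -> int:
    for atom in mol.GetAtoms():
        if atom.HasProp(_TAG) and atom.GetIntProp(_TAG) == tag:
            return atom.GetIdx()
    raise KeyError(f"no atom tagged {tag}")


def _form_bond(rw: Chem.RWMol, rule: BondRule, donor_tag: int, acceptor_tag: int) -> bool:
    """Apply one bond rule between tagged reactive-group atoms. In place.

    Returns False when the local chemistry does not fit (e.g. the marked
    donor atom lost its leaving partner already).  Atom indices shift on
    removal, so the anchor and acceptor are re-found by tag afterwards.
    """
    donor_idx = _tagged_atom(rw, donor_tag)
    donor = rw.GetAtomWithIdx(donor_idx)

    if rule.donor_group_type == "activated-anomeric":
        # marked atom is the anomeric hydroxyl O; its carbon is the new bond end
        carbons = [n for n in donor.GetNeighbors() if n.GetSymbol() == "C"]
        if len(carbons) != 1 or donor.GetDegree() != 1:
            return False
        anchor_tag = carbons[0].GetIntProp(_TAG)
        rw.RemoveAtom(donor_idx)
    elif rule.donor_group_type == "ketone":
        # marked atom is the carbonyl carbon; its =O leaves, C=N forms
        oxo = [
            n
            for n in donor.GetNeighbors()
            if n.GetSymbol() == "O"
            and rw.GetBondBetweenAtoms(donor_idx, n.GetIdx()).GetBondType()
            == Chem.BondType.DOUBLE
        ]
        if not oxo:
            return False
        anchor_tag = donor_tag
        rw.RemoveAtom(oxo[0].GetIdx())
    elif rule.donor_group_type == "carboxyl":
        # marked atom is the carboxyl carbon; its -OH leaves, amide forms
        hydroxyls = [
            n
            for n in donor.GetNeighbors()
            if n.GetSymbol() == "O"
            and n.GetDegree() == 1
            and rw.GetBondBetweenAtoms(donor_idx, n.GetIdx()).GetBondType()
            == Chem.BondType.SINGLE
        ]
        if not hydroxyls:
            return False
        anchor_tag = donor_tag
        rw.RemoveAtom(hydroxyls[0].GetIdx())
    else:
        return False

    anchor_idx = _tagged_atom(rw, anchor_tag)
    acceptor_idx = _tagged_atom(rw, acceptor_tag)
    if rw.GetBondBetweenAtoms(anchor_idx, acceptor_idx) is not None:
        return False
    order = Chem.BondType.DOUBLE if rule.bond_order == 2 else Chem.BondType.SINGLE
    rw.AddBond(anchor_idx, acceptor_idx, order)
    return True


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _distinct_orderings(monomer_ids: Sequence[str]) -> Iterable[tuple[str, ...]]:
    seen: set[tuple[str, ...]] = set()
    for perm in itertools.permutations(sorted(monomer_ids)):
        if perm not in seen:
            seen.add(perm)
            yield perm


def _compatible_choices(
    rule: BondRule, left: MonomerRecord, right: MonomerRecord
) -> Iterable[tuple[str, int, int]]:
    """(donor_side, donor_group, acceptor_group) choices for one junction."""
    for side, donor, acceptor in (("left", left, right), ("right", right, left)):
        for di, dgroup in enumerate(donor.reactive_groups):
            if dgroup.group_type != rule.donor_group_type:
                continue
            for ai, agroup in enumerate(acceptor.reactive_groups):
                if agroup.group_type != rule.acceptor_group_type:
                    continue
                yield side, di, ai


def assemble_backbones(
    monomer_ids: Sequence[str],
    kb: KnowledgeBase,
    max_backbones_per_set: int = 5000,
    cyclize: bool = False,
) -> list[BackboneCandidate]:
    """Enumerate linear backbones for one monomer multiset.

    Results are deduplicated by canonical SMILES and returned sorted; a
    multiset with no rule-compatible assembly yields an empty list.  With
    ``cyclize`` a terminal-to-terminal bond is additionally attempted on each
    completed chain when a compatible unused terminal group pair remains.
    """
    if not monomer_ids:
        return []
    records = [kb.monomers[mid] for mid in monomer_ids]
    if len(records) == 1:
        mono = records[0]
        return [
            BackboneCandidate(
                monomer_order=(mono.id,),
                bond_assignments=(),
                smiles=canonical_smiles(mono.smiles),
                monoisotopic_mass=mono.monoisotopic_mass,
            )
        ]

    rules = list(kb.bond_rules.values())
    results: dict[str, BackboneCandidate] = {}
    truncated = False

    for ordering in _distinct_orderings([m.id for m in records]):
        chain = [kb.monomers[mid] for mid in ordering]
        n_junctions = len(chain) - 1
        junction_options: list[list[tuple[BondRule, str, int, int]]] = []
        for j in range(n_junctions):
            options = [
                (rule, side, di, ai)
                for rule in rules
                for side, di, ai in _compatible_choices(rule, chain[j], chain[j + 1])
            ]
            junction_options.append(options)
        if any(not opts for opts in junction_options):
            continue

        for combo in itertools.product(*junction_options):
            # reactive-group accounting: one group per (position, junction),
            # no group consumed twice within a monomer position
            consumed: dict[int, set[int]] = {i: set() for i in range(len(chain))}
            ok = True
            assignments = []
            for j, (rule, side, di, ai) in enumerate(combo):
                donor_pos, acceptor_pos = (j, j + 1) if side == "left" else (j + 1, j)
                if di in consumed[donor_pos] or ai in consumed[acceptor_pos]:
                    ok = False
                    break
                consumed[donor_pos].add(di)
                consumed[acceptor_pos].add(ai)
                assignments.append(BondAssignment(rule.id, side, di, ai))
            if not ok:
                continue

            built = _build_chain(chain, combo)
            if built is None:
                continue
            mol, leaving_mass = built
            mass = ExactMolWt(mol)
            expected = sum(m.monoisotopic_mass for m in chain) - leaving_mass
            if abs(mass - expected) > MASS_TOL:  # pragma: no cover - safety net
                logger.warning("mass bookkeeping violation for %s; discarded", ordering)
                continue
            smiles = canonical_smiles(mol)
            if smiles not in results:
                if len(results) >= max_backbones_per_set:
                    truncated = True
                    break
                results[smiles] = BackboneCandidate(
                    monomer_order=ordering,
                    bond_assignments=tuple(assignments),
                    smiles=smiles,
                    monoisotopic_mass=mass,
                )
            if cyclize:
                cyc = _attempt_cyclization(chain, combo, consumed, kb)
                if cyc is not None and cyc[0] not in results:
                    if len(results) >= max_backbones_per_set:
                        truncated = True
                        break
                    cyc_smiles, cyc_mass, cyc_assign = cyc
                    results[cyc_smiles] = BackboneCandidate(
                        monomer_order=ordering,
                        bond_assignments=tuple(assignments) + (cyc_assign,),
                        smiles=cyc_smiles,
                        monoisotopic_mass=cyc_mass,
                    )
        if truncated:
            break

    if truncated:
        logger.warning(
            "backbone enumeration truncated at %d candidates for set %s",
            max_backbones_per_set,
            sorted(monomer_ids),
        )
    return sorted(results.values(), key=lambda c: (c.monoisotopic_mass, c.smiles))


def _combine_chain(chain: Sequence[MonomerRecord]) -> tuple[Chem.RWMol, list[int]]:
    """Disjoint union of the chain's monomers with per-position atom tags.

    Atom tags encode (position, original atom index) so reactive-group atoms
    stay addressable across edits.  Returns the editable mol and the tag
    offsets per position.
    """
    combined = Chem.RWMol()
    offsets: list[int] = []
    tag_base = 1
    for pos, mono in enumerate(chain):
        mol = mono.mol()
        offsets.append(tag_base)
        amap = {}
        for atom in mol.GetAtoms():
            new = Chem.Atom(atom.GetAtomicNum())
            new.SetFormalCharge(atom.GetFormalCharge())
            idx = combined.AddAtom(new)
            combined.GetAtomWithIdx(idx).SetIntProp(_TAG, tag_base + atom.GetIdx())
            amap[atom.GetIdx()] = idx
        for bond in mol.GetBonds():
            combined.AddBond(
                amap[bond.GetBeginAtomIdx()], amap[bond.GetEndAtomIdx()], bond.GetBondType()
            )
        tag_base += mol.GetNumAtoms()
    return combined, offsets


def _build_chain(
    chain: Sequence[MonomerRecord],
    combo: Sequence[tuple[BondRule, str, int, int]],
) -> tuple[Chem.Mol, float] | None:
    rw, offsets = _combine_chain(chain)
    leaving_mass = 0.0
    for j, (rule, side, di, ai) in enumerate(combo):
        donor_pos, acceptor_pos = (j, j + 1) if side == "left" else (j + 1, j)
        donor_group = chain[donor_pos].reactive_groups[di]
        acceptor_group = chain[acceptor_pos].reactive_groups[ai]
        donor_tag = offsets[donor_pos] + donor_group.atom_index - 1
        acceptor_tag = offsets[acceptor_pos] + acceptor_group.atom_index - 1
        try:
            if not _form_bond(rw, rule, donor_tag, acceptor_tag):
                return None
        except KeyError:
            return None
        leaving_mass += rule.leaving_mass
    mol = rw.GetMol()
    for atom in mol.GetAtoms():
        if atom.HasProp(_TAG):
            atom.ClearProp(_TAG)
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # noqa: BLE001 - invalid valence: discard this assembly
        return None
    if len(Chem.GetMolFrags(mol)) != 1:
        return None
    return mol, leaving_mass


def _attempt_cyclization(
    chain: Sequence[MonomerRecord],
    combo: Sequence[tuple[BondRule, str, int, int]],
    consumed: dict[int, set[int]],
    kb: KnowledgeBase,
) -> tuple[str, float, BondAssignment] | None:
    """Try one terminal-to-terminal bond on an assembled chain."""
    first, last = 0, len(chain) - 1
    for rule in kb.bond_rules.values():
        for donor_pos, acceptor_pos, side in ((last, first, "right"), (first, last, "left")):
            for di, dgroup in enumerate(chain[donor_pos].reactive_groups):
                if dgroup.group_type != rule.donor_group_type or di in consumed[donor_pos]:
                    continue
                for ai, agroup in enumerate(chain[acceptor_pos].reactive_groups):
                    if agroup.group_type != rule.acceptor_group_type or ai in consumed[acceptor_pos]:
                        continue
                    built = _build_ring(chain, combo, rule, donor_pos, acceptor_pos, di, ai)
                    if built is None:
                        continue
                    mol, leaving_mass = built
                    mass = ExactMolWt(mol)
                    return canonical_smiles(mol), mass, BondAssignment(rule.id, side, di, ai)
    return None


def _build_ring(
    chain: Sequence[MonomerRecord],
    combo: Sequence[tuple[BondRule, str, int, int]],
    rule: BondRule,
    donor_pos: int,
    acceptor_pos: int,
    di: int,
    ai: int,
) -> tuple[Chem.Mol, float] | None:
    rw, offsets = _combine_chain(chain)
    leaving_mass = 0.0
    for j, (jrule, side, jdi, jai) in enumerate(combo):
        dpos, apos = (j, j + 1) if side == "left" else (j + 1, j)
        dtag = offsets[dpos] + chain[dpos].reactive_groups[jdi].atom_index - 1
        atag = offsets[apos] + chain[apos].reactive_groups[jai].atom_index - 1
        try:
            if not _form_bond(rw, jrule, dtag, atag):
                return None
        except KeyError:
            return None
        leaving_mass += jrule.leaving_mass
    dtag = offsets[donor_pos] + chain[donor_pos].reactive_groups[di].atom_index - 1
    atag = offsets[acceptor_pos] + chain[acceptor_pos].reactive_groups[ai].atom_index - 1
    try:
        if not _form_bond(rw, rule, dtag, atag):
            return None
    except KeyError:
        return None
    leaving_mass += rule.leaving_mass
    mol = rw.GetMol()
    for atom in mol.GetAtoms():
        if atom.HasProp(_TAG):
            atom.ClearProp(_TAG)
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # noqa: BLE001
        return None
    if len(Chem.GetMolFrags(mol)) != 1:
        return None
    return mol, leaving_mass
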