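"""Postassembly-modification engine.

Tailoring enzymes detected in a BGC are modeled as graph-rewriting rules: a
substructure motif (SMILES) plus an ordered program of ``add`` / ``remove`` /
``connect`` / ``disconnect`` commands replayed against every embedding of the
motif in a candidate backbone.  ``add`` and ``remove`` act on atoms,
``connect`` and ``disconnect`` on bonds; e.g. an aminotransferase rule turns a
carbonyl into an amine by disconnecting and removing the carbonyl oxygen,
adding N/H/H atoms and connecting them, while a dehydratase creates a double
bond with a ``connect ... 2`` command.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt

from .knowledge_base import (
    Command,
    KnowledgeBase,
    MASS_TOL,
    ModificationRule,
    active_modification_rules,
)

logger = logging.getLogger(__name__)

_BOND_ORDERS = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


class RuleApplicationError(RuntimeError):
    """A command program could not be replayed at a site."""


@dataclass(frozen=True)
class MatureCandidate:
    """A backbone after zero or more modification-rule applications."""

    backbone_id: str
    applied_rules: tuple[tuple[str, str], ...]  # (rule_id, site signature)
    smiles: str
    monoisotopic_mass: float


# ---------------------------------------------------------------------------
# motif matching
# ---------------------------------------------------------------------------


def match_motif(structure: Chem.Mol, motif_smiles: str) -> list[tuple[int, ...]]:
    """All embeddings of ``motif_smiles`` in ``structure``.

    Returns one mapping per *site*: automorphic duplicates (matches covering
    the same atom set) are collapsed to a single representative, so a
    symmetric motif does not inflate the site count.
    """
    motif = Chem.MolFromSmiles(motif_smiles)
    if motif is None:
        raise ValueError(f"unparseable motif SMILES {motif_smiles!r}")
    matches = structure.GetSubstructMatches(motif, uniquify=True, maxMatches=10000)
    by_site: dict[frozenset[int], tuple[int, ...]] = {}
    for match in matches:
        site = frozenset(match)
        if site not in by_site:
            by_site[site] = match
    return [by_site[key] for key in sorted(by_site, key=lambda s: sorted(s))]


def site_signature(mapping: Sequence[int]) -> str:
    """Canonical, atom-order-independent signature of a site mapping."""
    return ",".join(str(i) for i in sorted(set(mapping)))


# ---------------------------------------------------------------------------
# command replay
# ---------------------------------------------------------------------------


def replay_commands(
    structure: Chem.Mol,
    commands: Sequence[Command],
    label_to_atom: Mapping[int, int],
) -> Chem.Mol:
    """Replay a command program against mapped atoms of ``structure``.

    ``label_to_atom`` maps 1-based motif labels to atom indices of
    ``structure``; atoms introduced by ``add`` extend the label space.  The
    result is sanitized; a valence violation or a reference to a missing
    label raises :class:`RuleApplicationError`.
    """
    rw = Chem.RWMol(structure)
    # Track labels robustly across removals via atom bookmarks on a tag prop.
    tag_of_label: dict[int, int] = {}
    for label, idx in label_to_atom.items():
        rw.GetAtomWithIdx(idx).SetIntProp("_gm_label_tag", label)
        tag_of_label[label] = label

    def atom_idx(label: int) -> int:
        for atom in rw.GetAtoms():
            if atom.HasProp("_gm_label_tag") and atom.GetIntProp("_gm_label_tag") == label:
                return atom.GetIdx()
        raise RuleApplicationError(f"command references missing atom label {label}")

    for cmd in commands:
        if cmd.verb == "add":
            label = cmd.args[0]
            if label in tag_of_label:
                raise RuleApplicationError(f"add reuses label {label}")
            atom = Chem.Atom(cmd.element)
            new_idx = rw.AddAtom(atom)
            rw.GetAtomWithIdx(new_idx).SetIntProp("_gm_label_tag", label)
            tag_of_label[label] = label
        elif cmd.verb == "remove":
            idx = atom_idx(cmd.args[0])
            rw.RemoveAtom(idx)  # incident bonds go with the atom
            tag_of_label.pop(cmd.args[0], None)
        elif cmd.verb == "connect":
            i, j, order = cmd.args
            if order not in _BOND_ORDERS:
                raise RuleApplicationError(f"unsupported bond order {order}")
            ai, aj = atom_idx(i), atom_idx(j)
            bond = rw.GetBondBetweenAtoms(ai, aj)
            if bond is None:
                rw.AddBond(ai, aj, _BOND_ORDERS[order])
            else:
                bond.SetBondType(_BOND_ORDERS[order])
        elif cmd.verb == "disconnect":
            ai, aj = atom_idx(cmd.args[0]), atom_idx(cmd.args[1])
            if rw.GetBondBetweenAtoms(ai, aj) is None:
                raise RuleApplicationError(
                    f"disconnect {cmd.args[0]} {cmd.args[1]}: no such bond"
                )
            rw.RemoveBond(ai, aj)
        else:  # pragma: no cover - parser rejects unknown verbs
            raise RuleApplicationError(f"unknown verb {cmd.verb}")

    product = rw.GetMol()
    for atom in product.GetAtoms():
        if atom.HasProp("_gm_label_tag"):
            atom.ClearProp("_gm_label_tag")
    try:
        Chem.SanitizeMol(product)
        product = Chem.RemoveHs(product)
    except Exception as exc:
        raise RuleApplicationError(f"product fails sanitization: {exc}") from exc
    return product


def apply_rule(
    structure: Chem.Mol, rule: ModificationRule, site: Sequence[int]
) -> Chem.Mol:
    """Apply one modification rule at one motif embedding.

    The observed mass change is checked against the rule's stored
    ``mass_delta``; a mismatch (or a valence violation during replay) raises
    :class:`RuleApplicationError` so the caller can skip the site.
    """
    label_to_atom = {pos + 1: atom for pos, atom in enumerate(site)}
    product = replay_commands(structure, rule.commands, label_to_atom)
    observed = ExactMolWt(product) - ExactMolWt(structure)
    if abs(observed - rule.mass_delta) > MASS_TOL:
        raise RuleApplicationError(
            f"{rule.id}: observed mass delta {observed:.4f} != stored {rule.mass_delta:.4f}"
        )
    return product


# ---------------------------------------------------------------------------
# enumeration over rules, sites, and combinations
# ---------------------------------------------------------------------------


def enumerate_mature(
    backbone_smiles: str,
    active_rules: Sequence[ModificationRule],
    backbone_id: str = "backbone",
    max_depth: int = 3,
    max_candidates: int = 2000,
) -> list[MatureCandidate]:
    """Unmodified backbone plus all rule applications up to ``max_depth``.

    Breadth-first over (structure, applied-rule trail): each active rule is
    tried at every matching site of every frontier structure; products are
    deduplicated by canonical SMILES.  Rules are iterated in sorted-id order,
    which together with the dedup makes the output independent of the
    caller's rule ordering.  Valence-illegal or mass-inconsistent
    applications are skipped with a logged reason.
    """
    base = Chem.MolFromSmiles(backbone_smiles)
    if base is None:
        raise ValueError(f"unparseable backbone SMILES {backbone_smiles!r}")
    base_canonical = Chem.MolToSmiles(base)
    rules = sorted(active_rules, key=lambda r: r.id)

    results: dict[str, MatureCandidate] = {
        base_canonical: MatureCandidate(
            backbone_id=backbone_id,
            applied_rules=(),
            smiles=base_canonical,
            monoisotopic_mass=ExactMolWt(base),
        )
    }
    frontier: list[tuple[Chem.Mol, tuple[tuple[str, str], ...]]] = [(base, ())]
    truncated = False

    for _depth in range(max_depth):
        next_frontier: list[tuple[Chem.Mol, tuple[tuple[str, str], ...]]] = []
        for mol, trail in frontier:
            for rule in rules:
                try:
                    sites = match_motif(mol, rule.motif_smiles)
                except ValueError:
                    logger.warning("rule %s: motif does not parse; skipped", rule.id)
                    continue
                for site in sites:
                    try:
                        product = apply_rule(mol, rule, site)
                    except RuleApplicationError as exc:
                        logger.debug("rule %s skipped at a site: %s", rule.id, exc)
                        continue
                    smiles = Chem.MolToSmiles(product)
                    if smiles in results:
                        continue
                    if len(results) >= max_candidates:
                        truncated = True
                        break
                    new_trail = trail + ((rule.id, site_signature(site)),)
                    results[smiles] = MatureCandidate(
                        backbone_id=backbone_id,
                        applied_rules=new_trail,
                        smiles=smiles,
                        monoisotopic_mass=ExactMolWt(product),
                    )
                    next_frontier.append((product, new_trail))
                if truncated:
                    break
            if truncated:
                break
        if truncated or not next_frontier:
            break
        frontier = next_frontier

    if truncated:
        logger.warning(
            "modification enumeration for %s truncated at %d candidates",
            backbone_id,
            max_candidates,
        )
    return sorted(results.values(), key=lambda c: (len(c.applied_rules), c.smiles))


def enumerate_mature_for_bgc(
    backbone_smiles: str,
    kb: KnowledgeBase,
    present_gene_classes: Iterable[str],
    backbone_id: str = "backbone",
    max_depth: int = 3,
    max_candidates: int = 2000,
) -> list[MatureCandidate]:
    """Convenience wrapper: activate rules from BGC gene content, then enumerate."""
    rules = active_modification_rules(kb, present_gene_classes)
    return enumerate_mature(
        backbone_smiles,
        rules,
        backbone_id=backbone_id,
        max_depth=max_depth,
        max_candidates=max_candidates,
    )
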