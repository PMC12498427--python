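"""Curated knowledge base for saccharide genome mining.

The knowledge base bundles four catalogs:

* **gene classes** -- enzyme families whose profile HMMs are searched against a
  genome (G classes; 50 in the packaged catalog),
* **monomers** -- sugar / aminocyclitol building blocks with 2D achiral SMILES
  and annotated reactive groups (20 secondary + 6 primary in the packaged
  catalog),
* **bond rules** -- the three fundamental inter-monomer bond-formation
  families (glycosidic, N-glycosidic/dehydrative, amide),
* **modification rules** -- tailoring-enzyme transformations encoded as a
  substructure motif plus an ordered graph-edit command program
  (49 in the packaged catalog).

Catalogs are stored as versioned TSV files so they stay diffable and
hand-curatable.  Atom indices in reactive groups and command programs are
1-based in SMILES atom-appearance order.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.Descriptors import ExactMolWt

RDLogger.DisableLog("rdApp.*")

# ---------------------------------------------------------------------------
# vocabulary and monoisotopic masses
# ---------------------------------------------------------------------------

#: Reactive-group vocabulary.  ``activated-anomeric`` marks the anomeric
#: hydroxyl standing in for the nucleotide-diphosphate (NDP/GDP/UDP/dTDP)
#: activating group of a sugar donor; the four carriers are chemically
#: interchangeable for 2D structure prediction, so a single placeholder is used.
REACTIVE_GROUP_TYPES = frozenset(
    {"hydroxyl", "amine", "activated-anomeric", "carboxyl", "ketone"}
)

#: Monoisotopic atomic masses (Da) used for elemental-formula accounting.
MONOISOTOPIC = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
}

MASS_TOL = 1e-4  # Da; tolerance for stored-vs-recomputed mass deltas


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a simple elemental formula such as ``H2O``.

    Supports one- or two-letter element symbols followed by an optional count
    (``C2H4O2``).  An empty formula or ``-`` has mass zero.
    """
    if not formula or formula == "-":
        return 0.0
    mass = 0.0
    i = 0
    while i < len(formula):
        if not formula[i].isupper():
            raise CatalogError(f"malformed formula {formula!r}")
        sym = formula[i]
        i += 1
        if i < len(formula) and formula[i].islower():
            sym += formula[i]
            i += 1
        count = 0
        while i < len(formula) and formula[i].isdigit():
            count = count * 10 + int(formula[i])
            i += 1
        if sym not in MONOISOTOPIC:
            raise CatalogError(f"unknown element {sym!r} in formula {formula!r}")
        mass += MONOISOTOPIC[sym] * max(count, 1)
    return mass


# ---------------------------------------------------------------------------
# validation failures
# ---------------------------------------------------------------------------


class CatalogError(ValueError):
    """Base class for knowledge-base validation failures."""


class MalformedSmilesError(CatalogError):
    """A catalog SMILES string does not parse."""


class DanglingReferenceError(CatalogError):
    """A record references an id absent from its target catalog."""


class CardinalityMismatchError(CatalogError):
    """Loaded catalog sizes disagree with the configured G / K."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneClassRecord:
    """One enzyme class searched for in genomes.

    ``monomer_roles`` lists monomers whose biosynthesis this class supports
    (a single gene class may serve several monomers); ``modification_roles``
    lists modification rules the class switches on.
    """

    id: str
    name: str
    hmm_ref: str
    monomer_roles: tuple[str, ...] = ()
    modification_roles: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReactiveGroup:
    """A reactive site on a monomer: group type + 1-based atom index."""

    group_type: str
    atom_index: int


@dataclass(frozen=True)
class MonomerRecord:
    id: str
    name: str
    smiles: str
    reactive_groups: tuple[ReactiveGroup, ...]
    required_gene_classes: frozenset[str]
    is_primary: bool
    monoisotopic_mass: float = 0.0

    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - guarded at load time
            raise MalformedSmilesError(self.smiles)
        return mol


@dataclass(frozen=True)
class BondRule:
    """One inter-monomer bond-formation family.

    ``leaving_composition`` is the elemental formula removed when the bond
    forms (water for all three packaged families once the NDP activating
    group is modeled as the anomeric hydroxyl placeholder).
    ``bond_order`` is the order of the newly formed bond.
    """

    id: str
    reaction_name: str
    donor_group_type: str
    acceptor_group_type: str
    leaving_composition: str
    bond_order: int = 1

    @property
    def leaving_mass(self) -> float:
        return formula_mass(self.leaving_composition)


@dataclass(frozen=True)
class Command:
    """One graph-edit command of a modification program.

    Verbs: ``add <label> <element>``, ``remove <label>``,
    ``connect <i> <j> <order>``, ``disconnect <i> <j>``.  Labels are 1-based:
    motif atoms come first in SMILES order, atoms introduced by ``add`` take
    the labels they declare.  ``remove`` deletes the atom together with any
    bonds still incident on it.
    """

    verb: str
    args: tuple[int, ...] = ()
    element: str = ""

    def __str__(self) -> str:
        if self.verb == "add":
            return f"add {self.args[0]} {self.element}"
        return f"{self.verb} {' '.join(str(a) for a in self.args)}"


def parse_command(text: str) -> Command:
    parts = text.split()
    if not parts:
        raise CatalogError("empty modification command")
    verb = parts[0]
    if verb == "add":
        if len(parts) != 3:
            raise CatalogError(f"malformed add command {text!r}")
        return Command("add", (int(parts[1]),), parts[2])
    if verb == "remove":
        return Command("remove", (int(parts[1]),))
    if verb == "connect":
        return Command("connect", (int(parts[1]), int(parts[2]), int(parts[3])))
    if verb == "disconnect":
        return Command("disconnect", (int(parts[1]), int(parts[2])))
    raise CatalogError(f"unknown command verb {verb!r}")


def parse_program(text: str) -> tuple[Command, ...]:
    """Parse a semicolon-separated command program; ``-`` is the identity."""
    text = text.strip()
    if not text or text == "-":
        return ()
    return tuple(parse_command(part) for part in text.split(";") if part.strip())


@dataclass(frozen=True)
class ModificationRule:
    id: str
    name: str
    enzyme_gene_classes: frozenset[str]
    motif_smiles: str
    commands: tuple[Command, ...]
    mass_delta: float

    def motif_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.motif_smiles)
        if mol is None:  # pragma: no cover - guarded at load time
            raise MalformedSmilesError(self.motif_smiles)
        return mol


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of replaying a modification rule on its own motif."""

    rule_id: str
    ok: bool
    product_smiles: str | None
    observed_mass_delta: float | None
    mass_delta_ok: bool
    messages: tuple[str, ...] = ()


@dataclass
class KnowledgeBaseConfig:
    """Configured catalog cardinalities and file locations."""

    G: int = 50
    K: int = 6
    gene_classes_path: str | Path | None = None
    monomers_path: str | Path | None = None
    bond_rules_path: str | Path | None = None
    modifications_path: str | Path | None = None


@dataclass
class KnowledgeBase:
    config: KnowledgeBaseConfig
    gene_classes: dict[str, GeneClassRecord] = field(default_factory=dict)
    monomers: dict[str, MonomerRecord] = field(default_factory=dict)
    bond_rules: dict[str, BondRule] = field(default_factory=dict)
    modifications: dict[str, ModificationRule] = field(default_factory=dict)

    # -- convenience views ------------------------------------------------
    @property
    def gene_class_ids(self) -> tuple[str, ...]:
        return tuple(self.gene_classes)

    def gene_class_index(self) -> dict[str, int]:
        """Stable gene-class id -> position map (presence-vector layout)."""
        return {gid: i for i, gid in enumerate(self.gene_classes)}

    @property
    def primary_monomers(self) -> tuple[MonomerRecord, ...]:
        return tuple(m for m in self.monomers.values() if m.is_primary)

    @property
    def secondary_monomers(self) -> tuple[MonomerRecord, ...]:
        return tuple(m for m in self.monomers.values() if not m.is_primary)

    def primary_index(self) -> dict[str, int]:
        return {m.id: j for j, m in enumerate(self.primary_monomers)}

    def canonical_serialization(self) -> str:
        """Deterministic text rendering used for idempotence checks."""
        lines = []
        for gid, gc in self.gene_classes.items():
            lines.append(
                f"G\t{gid}\t{gc.name}\t{gc.hmm_ref}\t"
                f"{','.join(gc.monomer_roles)}\t{','.join(gc.modification_roles)}"
            )
        for mid, m in self.monomers.items():
            groups = ";".join(f"{g.group_type}:{g.atom_index}" for g in m.reactive_groups)
            lines.append(
                f"M\t{mid}\t{m.smiles}\t{groups}\t"
                f"{','.join(sorted(m.required_gene_classes))}\t{int(m.is_primary)}\t"
                f"{m.monoisotopic_mass:.4f}"
            )
        for bid, b in self.bond_rules.items():
            lines.append(
                f"B\t{bid}\t{b.reaction_name}\t{b.donor_group_type}\t"
                f"{b.acceptor_group_type}\t{b.leaving_composition}\t{b.bond_order}"
            )
        for rid, r in self.modifications.items():
            prog = ";".join(str(c) for c in r.commands)
            lines.append(
                f"R\t{rid}\t{','.join(sorted(r.enzyme_gene_classes))}\t"
                f"{r.motif_smiles}\t{prog}\t{r.mass_delta:.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# TSV parsing
# ---------------------------------------------------------------------------


def _read_tsv(path: Path, expected_kind: str) -> list[dict[str, str]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise CatalogError(f"{path}: empty catalog file")
    header_meta = lines[0]
    if not header_meta.startswith("#glycomine-catalog"):
        raise CatalogError(f"{path}: missing versioned catalog header")
    meta = header_meta.split("\t")
    if len(meta) < 3 or meta[1] != expected_kind:
        raise CatalogError(
            f"{path}: catalog kind {meta[1] if len(meta) > 1 else '?'!r}, "
            f"expected {expected_kind!r}"
        )
    body = [ln for ln in lines[1:] if ln.strip() and not ln.startswith("#")]
    if not body:
        return []
    columns = body[0].split("\t")
    rows = []
    for ln in body[1:]:
        values = ln.split("\t")
        if len(values) != len(columns):
            raise CatalogError(f"{path}: row with {len(values)} fields, expected {len(columns)}")
        rows.append(dict(zip(columns, values)))
    return rows


def _split(field_value: str) -> tuple[str, ...]:
    field_value = field_value.strip()
    if not field_value or field_value == "-":
        return ()
    return tuple(part for part in field_value.split(";") if part)


def default_catalog_dir() -> Path:
    """Directory holding the packaged catalog TSV files."""
    return Path(importlib.resources.files("glycomine") / "data")


def strip_stereo(smiles: str) -> str:
    """Canonical SMILES with all stereochemistry removed."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MalformedSmilesError(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------


def load_knowledge_base(
    catalog_dir: str | Path | None = None,
    config: KnowledgeBaseConfig | None = None,
) -> KnowledgeBase:
    """Load and validate the four catalogs.

    Records are ordered deterministically by id.  Raises a named
    :class:`CatalogError` subclass on malformed SMILES, dangling
    cross-references, or cardinality mismatches against the config.
    """
    config = config or KnowledgeBaseConfig()
    base = Path(catalog_dir) if catalog_dir is not None else default_catalog_dir()
    gc_path = Path(config.gene_classes_path or base / "gene_classes.tsv")
    mono_path = Path(config.monomers_path or base / "monomers.tsv")
    bond_path = Path(config.bond_rules_path or base / "bond_rules.tsv")
    mod_path = Path(config.modifications_path or base / "modifications.tsv")

    kb = KnowledgeBase(config=config)

    # monomers ---------------------------------------------------------
    for row in sorted(_read_tsv(mono_path, "monomers"), key=lambda r: r["id"]):
        smiles = row["smiles"]
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise MalformedSmilesError(f"{row['id']}: {smiles!r}")
        clean = strip_stereo(smiles)
        if clean != Chem.MolToSmiles(Chem.MolFromSmiles(smiles)):
            smiles = clean  # stereo marks are stripped on load
            mol = Chem.MolFromSmiles(smiles)
        groups = []
        for token in _split(row["reactive_groups"]):
            gtype, _, idx = token.partition(":")
            if gtype not in REACTIVE_GROUP_TYPES:
                raise CatalogError(f"{row['id']}: unknown reactive group type {gtype!r}")
            atom_index = int(idx)
            if not 1 <= atom_index <= mol.GetNumAtoms():
                raise CatalogError(
                    f"{row['id']}: reactive-group atom index {atom_index} out of range"
                )
            atom = mol.GetAtomWithIdx(atom_index - 1)
            expected = {"hydroxyl": "O", "activated-anomeric": "O", "amine": "N",
                        "carboxyl": "C", "ketone": "C"}[gtype]
            if atom.GetSymbol() != expected:
                raise CatalogError(
                    f"{row['id']}: group {gtype} points at {atom.GetSymbol()}, "
                    f"expected {expected}"
                )
            groups.append(ReactiveGroup(gtype, atom_index))
        record = MonomerRecord(
            id=row["id"],
            name=row["name"],
            smiles=smiles,
            reactive_groups=tuple(groups),
            required_gene_classes=frozenset(_split(row["required_gene_classes"])),
            is_primary=row["is_primary"] == "1",
            monoisotopic_mass=ExactMolWt(mol),
        )
        if record.id in kb.monomers:
            raise CatalogError(f"duplicate monomer id {record.id}")
        if not record.is_primary and not record.required_gene_classes:
            raise CatalogError(f"{record.id}: secondary monomer without required gene classes")
        if record.is_primary and record.required_gene_classes:
            raise CatalogError(f"{record.id}: primary monomer lists required gene classes")
        kb.monomers[record.id] = record

    # modification rules ----------------------------------------------
    for row in sorted(_read_tsv(mod_path, "modifications"), key=lambda r: r["id"]):
        motif = row["motif_smiles"]
        if Chem.MolFromSmiles(motif) is None:
            raise MalformedSmilesError(f"{row['id']}: {motif!r}")
        rule = ModificationRule(
            id=row["id"],
            name=row["name"],
            enzyme_gene_classes=frozenset(_split(row["enzyme_gene_classes"])),
            motif_smiles=motif,
            commands=parse_program(row["commands"]),
            mass_delta=float(row["mass_delta"]),
        )
        if rule.id in kb.modifications:
            raise CatalogError(f"duplicate modification id {rule.id}")
        if not rule.enzyme_gene_classes:
            raise CatalogError(f"{rule.id}: modification rule without enzyme gene classes")
        kb.modifications[rule.id] = rule

    # gene classes -----------------------------------------------------
    for row in sorted(_read_tsv(gc_path, "gene_classes"), key=lambda r: r["id"]):
        record = GeneClassRecord(
            id=row["id"],
            name=row["name"],
            hmm_ref=row["hmm_ref"],
            monomer_roles=_split(row["monomer_roles"]),
            modification_roles=_split(row["modification_roles"]),
        )
        if record.id in kb.gene_classes:
            raise CatalogError(f"duplicate gene class id {record.id}")
        kb.gene_classes[record.id] = record

    # bond rules -------------------------------------------------------
    for row in sorted(_read_tsv(bond_path, "bond_rules"), key=lambda r: r["id"]):
        rule = BondRule(
            id=row["id"],
            reaction_name=row["reaction_name"],
            donor_group_type=row["donor_group_type"],
            acceptor_group_type=row["acceptor_group_type"],
            leaving_composition=row["leaving_composition"],
            bond_order=int(row.get("bond_order", "1")),
        )
        if rule.reaction_name not in {"glycosylation", "dehydration", "amidation", "ribosylation"}:
            raise CatalogError(f"{rule.id}: unknown reaction name {rule.reaction_name!r}")
        for gtype in (rule.donor_group_type, rule.acceptor_group_type):
            if gtype not in REACTIVE_GROUP_TYPES:
                raise CatalogError(f"{rule.id}: unknown reactive group type {gtype!r}")
        formula_mass(rule.leaving_composition)  # validates the formula
        kb.bond_rules[rule.id] = rule

    _validate_cross_references(kb)
    _validate_cardinalities(kb)
    return kb


def _validate_cross_references(kb: KnowledgeBase) -> None:
    for gc in kb.gene_classes.values():
        for mid in gc.monomer_roles:
            if mid not in kb.monomers:
                raise DanglingReferenceError(f"{gc.id}: unknown monomer role {mid!r}")
        for rid in gc.modification_roles:
            if rid not in kb.modifications:
                raise DanglingReferenceError(f"{gc.id}: unknown modification role {rid!r}")
    for m in kb.monomers.values():
        for gid in m.required_gene_classes:
            if gid not in kb.gene_classes:
                raise DanglingReferenceError(f"{m.id}: unknown gene class {gid!r}")
    for r in kb.modifications.values():
        for gid in r.enzyme_gene_classes:
            if gid not in kb.gene_classes:
                raise DanglingReferenceError(f"{r.id}: unknown gene class {gid!r}")


def _validate_cardinalities(kb: KnowledgeBase) -> None:
    if len(kb.gene_classes) != kb.config.G:
        raise CardinalityMismatchError(
            f"{len(kb.gene_classes)} gene classes loaded, config G={kb.config.G}"
        )
    n_primary = sum(m.is_primary for m in kb.monomers.values())
    if n_primary != kb.config.K:
        raise CardinalityMismatchError(
            f"{n_primary} primary monomers loaded, config K={kb.config.K}"
        )


def validate_modification_rule(rule: ModificationRule) -> ValidationReport:
    """Replay a rule's command program on its bare motif.

    The report states whether the replay yields a chemically valid, connected
    product and whether the observed motif->product mass change matches the
    stored ``mass_delta`` within :data:`MASS_TOL`.
    """
    from .modification_engine import replay_commands  # local import: avoids cycle

    motif = Chem.MolFromSmiles(rule.motif_smiles)
    if motif is None:
        return ValidationReport(rule.id, False, None, None, False, ("motif SMILES does not parse",))
    try:
        product = replay_commands(motif, rule.commands,
                                  {i + 1: i for i in range(motif.GetNumAtoms())})
    except Exception as exc:  # noqa: BLE001 - report carries the failure
        return ValidationReport(rule.id, False, None, None, False, (f"replay failed: {exc}",))
    messages: list[str] = []
    frags = Chem.GetMolFrags(product)
    if len(frags) != 1:
        messages.append(f"product has {len(frags)} fragments")
    observed = ExactMolWt(product) - ExactMolWt(motif)
    mass_ok = abs(observed - rule.mass_delta) <= MASS_TOL
    if not mass_ok:
        messages.append(
            f"mass delta mismatch: observed {observed:.4f}, stored {rule.mass_delta:.4f}"
        )
    ok = len(frags) == 1 and mass_ok
    return ValidationReport(
        rule_id=rule.id,
        ok=ok,
        product_smiles=Chem.MolToSmiles(product),
        observed_mass_delta=observed,
        mass_delta_ok=mass_ok,
        messages=tuple(messages),
    )


def active_modification_rules(
    kb: KnowledgeBase, present_gene_classes: Iterable[str]
) -> tuple[ModificationRule, ...]:
    """Rules whose enzyme gene classes are *all* present in the BGC.

    Multi-enzyme rules activate only when every listed class is detected.
    """
    present = set(present_gene_classes)
    return tuple(
        rule
        for rule in kb.modifications.values()
        if rule.enzyme_gene_classes <= present
    )
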