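"""Synthetic fixtures: toy catalogs, genomes, training pairs, and spectra.

Everything the test suite and the worked examples need is generated here from
an explicit seed, so fixtures are reproducible byte-for-byte and every
expectation can be computed from the returned truth tables without re-reading
fixture internals.  The toy monomer palette reuses real sugar graphs
(glucose, glucosamine, ribose, 6-deoxyhexose) so the chemistry paths run on
realistic valences.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .knowledge_base import KnowledgeBase, KnowledgeBaseConfig, load_knowledge_base
from .monomer_selection import SaccharideVector
from .spectral_matching import ADDUCTS, TheoreticalSpectrum, fragment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Plan for all synthetic inputs; the seed is mandatory."""

    seed: int
    # toy knowledge-base dimensions
    G: int = 6
    K: int = 2
    n_secondary: int = 3
    # genome / implant plan
    contig_id: str = "ctg1"
    contig_length: int = 200_000
    implant_classes: tuple[str, ...] = ()
    implant_positions: tuple[int, ...] = ()
    n_filler_proteins: int = 5
    protein_length: int = 100
    # training-pair plan
    alpha: float = 0.9
    beta: float = 0.05
    gamma: float = 0.3
    n_pairs: int = 500
    bgc_gene_rate: float = 0.5
    # spectrum noise plan
    max_cuts: int = 2
    dropout: float = 0.0
    n_noise_peaks: int = 0
    mass_shift: float = 0.0
    jitter_da: float = 0.0
    adduct: str = "[M+H]+"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "dropout", "bgc_gene_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# toy knowledge base
# ---------------------------------------------------------------------------

_TOY_SECONDARY = [
    # (id, name, smiles, reactive groups, required classes by position)
    ("t_aminohexose", "toy 2-aminohexose", "NC1C(O)C(O)C(CO)OC1O",
     "activated-anomeric:12;hydroxyl:4;hydroxyl:6;hydroxyl:9;amine:1", (0, 1)),
    ("t_deoxyhexose", "toy 6-deoxyhexose", "CC1OC(O)C(O)C(O)C1O",
     "activated-anomeric:5;hydroxyl:7;hydroxyl:9;hydroxyl:11", (1, 2)),
    ("t_aldopentose", "toy aldopentose", "OCC1OC(O)C(O)C1O",
     "activated-anomeric:6;hydroxyl:1;hydroxyl:8;hydroxyl:10", (3,)),
]

_TOY_PRIMARY = [
    ("t_glucose", "toy glucose", "OCC1OC(O)C(O)C(O)C1O",
     "activated-anomeric:6;hydroxyl:1;hydroxyl:8;hydroxyl:10;hydroxyl:12"),
    ("t_xylose", "toy xylose", "OC1OCC(O)C(O)C1O",
     "activated-anomeric:1;hydroxyl:6;hydroxyl:8;hydroxyl:10"),
]

_TOY_MODIFICATIONS = [
    # (id, name, enzyme class positions, motif, commands, mass delta)
    ("tmod_omethyl", "toy O-methyltransferase", (4,), "CO",
     "add 3 C;connect 2 3 1", 14.0157),
    ("tmod_deoxy", "toy deoxygenation", (4, 5), "CO",
     "disconnect 1 2;remove 2", -15.9949),
]


def write_toy_catalogs(directory: str | Path, spec: FixtureSpec) -> KnowledgeBaseConfig:
    """Write a small, fully valid catalog set under ``directory``.

    The toy catalogs have ``spec.G`` gene classes, ``spec.K`` primary and
    ``spec.n_secondary`` secondary monomers, one glycosylation bond rule, and
    two modification rules.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    class_ids = [f"gcT{i + 1}" for i in range(spec.G)]
    secondary = _TOY_SECONDARY[: spec.n_secondary]
    primary = _TOY_PRIMARY[: spec.K]
    if len(secondary) < spec.n_secondary or len(primary) < spec.K:
        raise ValueError("toy palette smaller than requested dimensions")

    mono_lines = [
        "#glycomine-catalog\tmonomers\tv1",
        "id\tname\tsmiles\treactive_groups\trequired_gene_classes\tis_primary",
    ]
    roles: dict[str, list[str]] = {gid: [] for gid in class_ids}
    for mid, name, smiles, groups, class_pos in secondary:
        classes = [class_ids[p] for p in class_pos if p < spec.G]
        if not classes:
            classes = [class_ids[0]]
        for gid in classes:
            roles[gid].append(mid)
        mono_lines.append(f"{mid}\t{name}\t{smiles}\t{groups}\t{';'.join(classes)}\t0")
    for mid, name, smiles, groups in primary:
        mono_lines.append(f"{mid}\t{name}\t{smiles}\t{groups}\t-\t1")
    (directory / "monomers.tsv").write_text("\n".join(mono_lines) + "\n")

    mod_lines = [
        "#glycomine-catalog\tmodifications\tv1",
        "id\tname\tenzyme_gene_classes\tmotif_smiles\tcommands\tmass_delta",
    ]
    mod_roles: dict[str, list[str]] = {gid: [] for gid in class_ids}
    for rid, name, class_pos, motif, commands, delta in _TOY_MODIFICATIONS:
        classes = [class_ids[p] for p in class_pos if p < spec.G] or [class_ids[-1]]
        for gid in classes:
            mod_roles[gid].append(rid)
        mod_lines.append(f"{rid}\t{name}\t{';'.join(classes)}\t{motif}\t{commands}\t{delta}")
    (directory / "modifications.tsv").write_text("\n".join(mod_lines) + "\n")

    gc_lines = [
        "#glycomine-catalog\tgene_classes\tv1",
        "id\tname\thmm_ref\tmonomer_roles\tmodification_roles",
    ]
    for gid in class_ids:
        gc_lines.append(
            f"{gid}\ttoy enzyme {gid}\t{gid}\t{';'.join(roles[gid]) or '-'}\t"
            f"{';'.join(mod_roles[gid]) or '-'}"
        )
    (directory / "gene_classes.tsv").write_text("\n".join(gc_lines) + "\n")

    bond_lines = [
        "#glycomine-catalog\tbond_rules\tv1",
        "id\treaction_name\tdonor_group_type\tacceptor_group_type\tleaving_composition\tbond_order",
        "bond_glyc\tglycosylation\tactivated-anomeric\thydroxyl\tH2O\t1",
        "bond_nglyc\tdehydration\tactivated-anomeric\tamine\tH2O\t1",
        "bond_amide\tamidation\tcarboxyl\tamine\tH2O\t1",
    ]
    (directory / "bond_rules.tsv").write_text("\n".join(bond_lines) + "\n")

    return KnowledgeBaseConfig(
        G=spec.G,
        K=spec.K,
        gene_classes_path=directory / "gene_classes.tsv",
        monomers_path=directory / "monomers.tsv",
        bond_rules_path=directory / "bond_rules.tsv",
        modifications_path=directory / "modifications.tsv",
    )


def make_toy_kb(directory: str | Path, spec: FixtureSpec) -> KnowledgeBase:
    config = write_toy_catalogs(directory, spec)
    return load_knowledge_base(config=config)


# ---------------------------------------------------------------------------
# profiles and genomes
# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def class_consensus(spec: FixtureSpec, gene_class: str) -> str:
    """Deterministic consensus protein for one toy gene class."""
    sub = np.random.default_rng(
        np.random.SeedSequence([spec.seed, sum(ord(c) for c in gene_class)])
    )
    return _random_protein(sub, spec.protein_length)


def build_fixture_profiles(spec: FixtureSpec, gene_classes: Sequence[str]):
    """Build one profile HMM per gene class from a small mutated MSA.

    Each class gets a seeded consensus protein; eight copies with 5% point
    mutations form the alignment pyhmmer's builder turns into a profile
    named after the class.
    """
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    profiles = []
    for gene_class in gene_classes:
        consensus = class_consensus(spec, gene_class)
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 7, sum(ord(c) for c in gene_class)])
        )
        seqs = []
        for i in range(8):
            residues = list(consensus)
            n_mut = max(1, int(0.05 * len(residues)))
            for pos in rng.choice(len(residues), size=n_mut, replace=False):
                residues[pos] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
            seqs.append(
                pyhmmer.easel.TextSequence(
                    name=f"{gene_class}_{i}".encode(), sequence="".join(residues)
                )
            )
        msa = pyhmmer.easel.TextMSA(
            name=gene_class.encode(), sequences=seqs
        ).digitize(alphabet)
        hmm, _, _ = builder.build_msa(msa, background)
        profiles.append(hmm)
    return profiles


def make_toy_genome(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Protein FASTA with implanted gene-class consensi among random filler.

    Implants carry ``loc=`` coordinate tokens at the planned loci; the truth
    table (TSV) records class, protein id, and coordinates.  Returns paths
    and the truth rows.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    positions = list(spec.implant_positions)
    if len(positions) < len(spec.implant_classes):
        # lay out remaining implants 2 kb apart after the last planned locus
        next_pos = (positions[-1] + 2000) if positions else 50_000
        while len(positions) < len(spec.implant_classes):
            positions.append(next_pos)
            next_pos += 2000
    records = []
    truth_rows = []
    for i, (gene_class, pos) in enumerate(zip(spec.implant_classes, positions)):
        seq = class_consensus(spec, gene_class)
        start, end = pos, pos + 3 * len(seq) - 1
        if end > spec.contig_length:
            raise ValueError(f"implant for {gene_class} beyond contig end")
        pid = f"implant_{i}_{gene_class}"
        records.append((pid, seq, start, end))
        truth_rows.append((pid, gene_class, spec.contig_id, start, end))
    filler_start = 5_000
    for i in range(spec.n_filler_proteins):
        seq = _random_protein(rng, spec.protein_length)
        start = filler_start + i * 400
        end = start + 3 * len(seq) - 1
        records.append((f"filler_{i}", seq, start, end))

    fasta_path = out_dir / "proteins.fasta"
    lines = []
    for pid, seq, start, end in records:
        lines.append(f">{pid} loc={spec.contig_id}:{start}-{end}:+")
        lines.append(seq)
    fasta_path.write_text("\n".join(lines) + "\n")

    truth_path = out_dir / "genome_truth.tsv"
    truth_lines = ["protein_id\tgene_class\tcontig\tstart\tend"]
    for row in truth_rows:
        truth_lines.append("\t".join(str(x) for x in row))
    truth_path.write_text("\n".join(truth_lines) + "\n")

    return {
        "fasta": fasta_path,
        "truth": truth_path,
        "contig_lengths": {spec.contig_id: spec.contig_length},
        "truth_rows": truth_rows,
    }


# ---------------------------------------------------------------------------
# training pairs
# ---------------------------------------------------------------------------


def make_training_pairs(
    spec: FixtureSpec,
) -> list[tuple[SaccharideVector, tuple[int, ...]]]:
    """Draw (saccharide, BGC) pairs from the generative model itself.

    For each pair: b_i ~ Bernoulli(bgc_gene_rate); g_i | b_i follows the
    four-case table with the plan's true (alpha, beta); m_j ~
    Bernoulli(gamma).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    pairs = []
    for _ in range(spec.n_pairs):
        b = (rng.random(spec.G) < spec.bgc_gene_rate).astype(int)
        u = rng.random(spec.G)
        g = np.where(b == 1, (u < spec.alpha), (u < spec.beta)).astype(int)
        m = (rng.random(spec.K) < spec.gamma).astype(int)
        pairs.append((SaccharideVector(g=tuple(g.tolist()), m=tuple(m.tolist())), tuple(b.tolist())))
    return pairs


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def make_spectrum(
    structure_smiles: str,
    spec: FixtureSpec,
    title: str = "fixture",
) -> dict:
    """Noisy MGF record from a structure's theoretical fragments.

    Fragments are computed at ``spec.max_cuts``, dropped out with probability
    ``spec.dropout``, jittered uniformly within ``+-jitter_da``, shifted by
    the plan's global ``mass_shift``, and mixed with uniform-random noise
    peaks.  The title embeds truth metadata (planted count, shift).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 31]))
    theo = fragment(structure_smiles, max_cuts=spec.max_cuts)
    adduct_delta = ADDUCTS[spec.adduct]
    planted = []
    for frag in theo.fragments:
        if rng.random() < spec.dropout:
            continue
        jitter = rng.uniform(-spec.jitter_da, spec.jitter_da) if spec.jitter_da else 0.0
        planted.append(frag.mass + spec.mass_shift + adduct_delta + jitter)
    lo = 50.0
    hi = theo.intact_mass + adduct_delta + 50.0
    noise = [float(rng.uniform(lo, hi)) for _ in range(spec.n_noise_peaks)]
    peaks = sorted(
        [(mz, 100.0) for mz in planted] + [(mz, float(rng.uniform(1.0, 50.0))) for mz in noise]
    )
    precursor = theo.intact_mass + spec.mass_shift + adduct_delta
    full_title = (
        f"{title} truth_planted={len(planted)} truth_shift={spec.mass_shift:.4f}"
    )
    return {
        "title": full_title,
        "pepmass": precursor,
        "charge": 1,
        "peaks": peaks,
        "n_planted": len(planted),
        "theoretical": theo,
    }


def write_mgf(records: Sequence[dict], path: str | Path) -> Path:
    """Minimal deterministic MGF writer for fixture records."""
    path = Path(path)
    blocks = []
    for rec in records:
        lines = [
            "BEGIN IONS",
            f"TITLE={rec['title']}",
            f"PEPMASS={rec['pepmass']:.5f}",
            f"CHARGE={rec.get('charge', 1)}+",
        ]
        for mz, intensity in rec["peaks"]:
            lines.append(f"{mz:.5f} {intensity:.2f}")
        lines.append("END IONS")
        blocks.append("\n".join(lines))
    path.write_text("\n\n".join(blocks) + "\n")
    return path
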