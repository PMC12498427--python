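"""Genome annotation and saccharide-BGC delimitation.

Proteins are scanned against per-gene-class profile HMMs; every significant
hit seeds a region extended 10 kb upstream and downstream (clipped to contig
bounds), and overlapping extensions on one contig are merged.  Each region is
then reduced to the binary gene-class presence vector consumed by the
monomer-selection models.

Live profile search runs through pyhmmer; alternatively a HMMER ``--tblout``
table or a plain annotation TSV can be supplied, so the downstream pipeline
is usable without profile databases.  Coordinates are 1-based inclusive
(GenBank convention); strand is recorded but ignored downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .knowledge_base import KnowledgeBase

DEFAULT_WINDOW_BP = 10_000
DEFAULT_EVALUE_CUTOFF = 1e-5

_LOC_RE = re.compile(r"loc=(?P<contig>[^:\s]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with optional genomic location metadata."""

    id: str
    sequence: str
    contig: str | None = None
    start: int | None = None  # 1-based inclusive, nucleotide
    end: int | None = None
    strand: str = "+"


@dataclass(frozen=True)
class GeneHit:
    gene_class_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    evalue: float
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"hit {self.protein_id}: start {self.start} > end {self.end}")
        if self.evalue < 0:
            raise ValueError(f"hit {self.protein_id}: negative e-value")


@dataclass(frozen=True)
class BGCRegion:
    contig_id: str
    start: int
    end: int
    hits: tuple[GeneHit, ...]

    @property
    def gene_classes(self) -> frozenset[str]:
        return frozenset(hit.gene_class_id for hit in self.hits)


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Protein FASTA; an optional ``loc=contig:start-end:+`` token in the
    description carries genomic coordinates."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        match = _LOC_RE.search(rec.description)
        if match:
            records.append(
                ProteinRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    contig=match["contig"],
                    start=int(match["start"]),
                    end=int(match["end"]),
                    strand=match["strand"],
                )
            )
        else:
            records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def read_genbank_proteins(path: str | Path) -> tuple[list[ProteinRecord], dict[str, int]]:
    """CDS translations plus contig lengths from a GenBank file.

    Nucleotide records are not gene-called ab initio: only annotated CDS
    features with a translation (or an in-frame nucleotide span) are used.
    """
    proteins: list[ProteinRecord] = []
    contig_lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        contig_lengths[rec.id] = len(rec.seq)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if "translation" in feat.qualifiers:
                seq = feat.qualifiers["translation"][0]
            else:
                seq = str(feat.extract(rec.seq).translate(to_stop=True))
            pid = feat.qualifiers.get("locus_tag", feat.qualifiers.get("protein_id", ["cds"]))[0]
            proteins.append(
                ProteinRecord(
                    id=pid,
                    sequence=seq,
                    contig=rec.id,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                )
            )
    return proteins, contig_lengths


def read_annotation_tsv(path: str | Path) -> list[GeneHit]:
    """Precomputed-annotation bypass: TSV of
    (protein_id, gene_class, evalue, contig, start, end, strand)."""
    hits = []
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    for ln in lines[1:]:
        if not ln.strip() or ln.startswith("#"):
            continue
        row = dict(zip(header, ln.split("\t")))
        hits.append(
            GeneHit(
                gene_class_id=row["gene_class"],
                contig_id=row["contig"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row.get("strand", "+"),
                evalue=float(row["evalue"]),
                protein_id=row["protein_id"],
            )
        )
    return hits


def parse_hmmer_tblout(path: str | Path) -> list[tuple[str, str, float]]:
    """Parse HMMER3 ``--tblout`` rows into (target, query, full-seq e-value).

    The format is whitespace-delimited with a free-text description tail;
    fields 1, 3 and 5 (1-based) are taken bit-exactly as printed.
    """
    rows = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split()
        if len(fields) < 5:
            raise ValueError(f"malformed tblout row: {ln!r}")
        rows.append((fields[0], fields[2], float(fields[4])))
    return rows


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def annotate_proteins(
    proteins: Sequence[ProteinRecord],
    profiles,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[GeneHit]:
    """Search proteins against gene-class profile HMMs (via pyhmmer).

    ``profiles`` is a sequence of ``pyhmmer.plan7.HMM`` objects (or a path to
    an HMM flatfile); each profile's name must be a gene class id or a
    catalog ``hmm_ref``.  One hit is kept per protein under the
    one-class-per-gene policy: the best (lowest e-value) class wins.

    Proteins without genomic coordinates are laid out head-to-tail on a
    pseudo-contig named ``proteome`` (1 bp per residue * 3), so windowing
    still applies.
    """
    import pyhmmer

    if not proteins:
        return []
    if isinstance(profiles, (str, Path)):
        with pyhmmer.plan7.HMMFile(str(profiles)) as fh:
            profiles = list(fh)
    if not profiles:
        raise ValueError("no profile HMMs supplied")

    alphabet = profiles[0].alphabet
    digital = [
        pyhmmer.easel.TextSequence(name=p.id.encode(), sequence=p.sequence).digitize(alphabet)
        for p in proteins
    ]
    def _as_str(name) -> str:
        return name.decode() if isinstance(name, bytes) else str(name)

    best: dict[str, tuple[float, str]] = {}
    for top_hits in pyhmmer.hmmsearch(profiles, digital):
        query_name = _as_str(top_hits.query.name)
        for hit in top_hits:
            if hit.evalue > evalue_cutoff:
                continue
            pid = _as_str(hit.name)
            if pid not in best or hit.evalue < best[pid][0]:
                best[pid] = (hit.evalue, query_name)

    by_id = {p.id: p for p in proteins}
    hits = []
    offset = 1
    pseudo_start: dict[str, int] = {}
    for p in proteins:  # deterministic pseudo-layout in input order
        pseudo_start[p.id] = offset
        offset += 3 * len(p.sequence)
    for pid in sorted(best):
        evalue, gene_class = best[pid]
        prot = by_id[pid]
        if prot.contig is not None:
            contig, start, end = prot.contig, prot.start, prot.end
        else:
            contig = "proteome"
            start = pseudo_start[pid]
            end = start + 3 * len(prot.sequence) - 1
        hits.append(
            GeneHit(
                gene_class_id=gene_class,
                contig_id=contig,
                start=int(start),
                end=int(end),
                strand=prot.strand,
                evalue=evalue,
                protein_id=pid,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# windowing and presence vectors
# ---------------------------------------------------------------------------


def window_regions(
    hits: Iterable[GeneHit],
    contig_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW_BP,
) -> list[BGCRegion]:
    """Extend each hit by ``window`` bp both ways, clip, and merge overlaps.

    Merging is order-independent: hits are sorted internally, so shuffling
    the input yields identical regions.
    """
    by_contig: dict[str, list[GeneHit]] = {}
    for hit in hits:
        if hit.contig_id not in contig_lengths:
            raise ValueError(f"hit on unknown contig {hit.contig_id!r}")
        length = contig_lengths[hit.contig_id]
        if hit.end > length:
            raise ValueError(
                f"hit {hit.protein_id} end {hit.end} beyond contig length {length}"
            )
        by_contig.setdefault(hit.contig_id, []).append(hit)

    regions: list[BGCRegion] = []
    for contig in sorted(by_contig):
        length = contig_lengths[contig]
        contig_hits = sorted(by_contig[contig], key=lambda h: (h.start, h.end, h.protein_id))
        intervals = [
            (max(1, h.start - window), min(length, h.end + window), h) for h in contig_hits
        ]
        intervals.sort(key=lambda iv: (iv[0], iv[1]))
        current_start, current_end = intervals[0][0], intervals[0][1]
        current_hits = [intervals[0][2]]
        for start, end, hit in intervals[1:]:
            if start <= current_end:
                current_end = max(current_end, end)
                current_hits.append(hit)
            else:
                regions.append(
                    BGCRegion(contig, current_start, current_end, tuple(current_hits))
                )
                current_start, current_end, current_hits = start, end, [hit]
        regions.append(BGCRegion(contig, current_start, current_end, tuple(current_hits)))
    return regions


def presence_vector(region: BGCRegion, kb: KnowledgeBase) -> tuple[int, ...]:
    """Binary vector b over the knowledge base's gene classes: b_i = 1 iff
    class i has at least one hit in the region (multiplicity- and
    strand-invariant)."""
    index = kb.gene_class_index()
    b = [0] * len(index)
    for hit in region.hits:
        if hit.gene_class_id not in index:
            raise ValueError(f"unknown gene class {hit.gene_class_id!r} in region hits")
        b[index[hit.gene_class_id]] = 1
    return tuple(b)


def regions_to_bed(regions: Sequence[BGCRegion]) -> str:
    """BED-like TSV export (0-based half-open coordinates on export)."""
    lines = ["#contig\tstart\tend\tn_hits\tgene_classes"]
    for r in regions:
        lines.append(
            f"{r.contig_id}\t{r.start - 1}\t{r.end}\t{len(r.hits)}\t"
            + ",".join(sorted(r.gene_classes))
        )
    return "\n".join(lines) + "\n"
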