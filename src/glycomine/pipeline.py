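"""End-to-end orchestration: genome -> ranked candidates -> spectral matches.

The pipeline chains the stage modules: BGC detection (annotation TSV or
protein FASTA + profile HMMs), probabilistic monomer-set ranking, backbone
assembly, postassembly modification, and optional spectral search.  Every
stage writes its artifact (TSV/CSV) and reports its counts in a JSON run
report; a run is a deterministic function of (inputs, config, seed).

Also hosts the benchmarking utilities: path-fingerprint Tanimoto similarity
and per-threshold correct-prediction counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from . import bgc_detection, modification_engine, monomer_selection, spectral_matching
from .backbone_assembly import assemble_backbones
from .knowledge_base import KnowledgeBase, load_knowledge_base
from .monomer_selection import (
    EnumerationLimits,
    ModelParams,
    SaccharideVector,
    train_parameters,
)

logger = logging.getLogger(__name__)

DEFAULT_TRAINING_TABLE = "training_pairs_synthetic.tsv"


@dataclass
class PipelineConfig:
    """Resolved defaults for every stage; logged verbatim with each run."""

    catalog_dir: str | None = None
    G: int = 50  # expected gene-class count of the catalog
    K: int = 6  # expected primary-monomer count
    window_bp: int = bgc_detection.DEFAULT_WINDOW_BP
    evalue_cutoff: float = bgc_detection.DEFAULT_EVALUE_CUTOFF
    model: str = "probabilistic"  # or "baseline"
    max_monomers: int = 7
    max_primary: int = 2
    max_multiplicity: int = 3
    top_n: int = 500
    relax_eligibility: bool = False
    max_sets_to_assemble: int = 500
    max_backbones_per_set: int = 5000
    modification_depth: int = 3
    max_mature_per_backbone: int = 2000
    cyclize: bool = False
    fragment_tol_da: float = spectral_matching.DEFAULT_FRAGMENT_TOL_DA
    precursor_tol_ppm: float = spectral_matching.DEFAULT_PRECURSOR_TOL_PPM
    adducts: tuple[str, ...] = ("[M+H]+", "[M-H]-", "[M+NH3]-")
    max_cuts: int = 2
    n_decoys: int = 999
    p_value_threshold: float = spectral_matching.DEFAULT_PVALUE_THRESHOLD
    variable: bool = False
    shift_bounds: tuple[float, float] = (-500.0, 500.0)
    seed: int = 0
    alpha: float | None = None  # set all three to bypass training
    beta: float | None = None
    gamma: float | None = None

    def limits(self) -> EnumerationLimits:
        return EnumerationLimits(
            max_monomers=self.max_monomers,
            max_primary=self.max_primary,
            max_multiplicity=self.max_multiplicity,
            top_n=self.top_n,
            relax_eligibility=self.relax_eligibility,
        )

    def search_config(self) -> spectral_matching.SearchConfig:
        return spectral_matching.SearchConfig(
            fragment_tol_da=self.fragment_tol_da,
            precursor_tol_ppm=self.precursor_tol_ppm,
            adducts=tuple(self.adducts),
            max_cuts=self.max_cuts,
            n_decoys=self.n_decoys,
            p_value_threshold=self.p_value_threshold,
            variable=self.variable,
            shift_bounds=tuple(self.shift_bounds),
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# default model parameters
# ---------------------------------------------------------------------------


def load_training_table(path: str | Path) -> list[tuple[SaccharideVector, tuple[int, ...]]]:
    """Read a training table of g/m/b bit-string columns."""
    pairs = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    for ln in lines[1:]:
        if not ln.strip() or ln.startswith("#"):
            continue
        row = dict(zip(header, ln.split("\t")))
        g = tuple(int(ch) for ch in row["g"])
        m = tuple(int(ch) for ch in row["m"])
        b = tuple(int(ch) for ch in row["b"])
        pairs.append((SaccharideVector(g=g, m=m), b))
    return pairs


def default_params(kb: KnowledgeBase, config: PipelineConfig) -> ModelParams:
    """Model parameters: explicit config values, else MLE from the packaged
    training table."""
    if None not in (config.alpha, config.beta, config.gamma):
        return ModelParams(config.alpha, config.beta, config.gamma)
    base = Path(config.catalog_dir) if config.catalog_dir else None
    from .knowledge_base import default_catalog_dir

    table = (base or default_catalog_dir()) / DEFAULT_TRAINING_TABLE
    params, _counts = train_parameters(load_training_table(table))
    return params


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------


def run_pipeline(
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    annotation_tsv: str | Path | None = None,
    protein_fasta: str | Path | None = None,
    profiles=None,
    contig_lengths: dict[str, int] | None = None,
    spectra_mgf: str | Path | None = None,
    kb: KnowledgeBase | None = None,
    params: ModelParams | None = None,
) -> dict:
    """Execute detection -> selection -> assembly -> modification -> search.

    Accepts either a precomputed annotation TSV or a protein FASTA plus
    profile HMMs.  Contig lengths default to the furthest hit plus one
    window.  All intermediate artifacts are written under ``out_dir``;
    returns the run report (also written as ``run_report.json``).
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(dataclasses.asdict(config)), "stages": {}}

    from .knowledge_base import KnowledgeBaseConfig

    kb = kb or load_knowledge_base(
        config.catalog_dir, KnowledgeBaseConfig(G=config.G, K=config.K)
    )
    params = params or default_params(kb, config)
    report["params"] = {"alpha": params.alpha, "beta": params.beta, "gamma": params.gamma}

    # stage 1: annotation -------------------------------------------------
    try:
        if annotation_tsv is not None:
            hits = bgc_detection.read_annotation_tsv(annotation_tsv)
        elif protein_fasta is not None:
            proteins = bgc_detection.read_protein_fasta(protein_fasta)
            hits = bgc_detection.annotate_proteins(proteins, profiles, config.evalue_cutoff)
        else:
            raise ValueError("either annotation_tsv or protein_fasta is required")
    except Exception as exc:
        report["stages"]["annotation"] = {"error": str(exc)}
        _write_report(out_dir, report)
        raise
    report["stages"]["annotation"] = {"n_hits": len(hits)}

    # stage 2: regions + presence vectors --------------------------------
    if contig_lengths is None:
        contig_lengths = {}
        for hit in hits:
            contig_lengths[hit.contig_id] = max(
                contig_lengths.get(hit.contig_id, 0), hit.end + config.window_bp
            )
    regions = bgc_detection.window_regions(hits, contig_lengths, config.window_bp)
    (out_dir / "regions.bed.tsv").write_text(bgc_detection.regions_to_bed(regions))
    report["stages"]["regions"] = {"n_regions": len(regions)}

    # stages 3-5 per region ----------------------------------------------
    candidate_rows = []
    n_sets_total = n_backbones_total = n_mature_total = 0
    for ri, region in enumerate(regions):
        vector = bgc_detection.presence_vector(region, kb)
        if config.model == "baseline":
            ranked = monomer_selection.rank_sets_baseline(vector, kb, config.limits())
        else:
            ranked = monomer_selection.enumerate_ranked_sets(vector, kb, params, config.limits())
        n_sets_total += len(ranked)
        present_classes = [
            gid for gid, bit in zip(kb.gene_class_ids, vector) if bit
        ]
        for rset in ranked[: config.max_sets_to_assemble]:
            backbones = assemble_backbones(
                rset.monomer_ids, kb, config.max_backbones_per_set, config.cyclize
            )
            n_backbones_total += len(backbones)
            for bi, backbone in enumerate(backbones):
                backbone_id = f"r{ri}_s{rset.rank}_b{bi}"
                mature = modification_engine.enumerate_mature_for_bgc(
                    backbone.smiles,
                    kb,
                    present_classes,
                    backbone_id=backbone_id,
                    max_depth=config.modification_depth,
                    max_candidates=config.max_mature_per_backbone,
                )
                n_mature_total += len(mature)
                for mi, cand in enumerate(mature):
                    applied = ";".join(f"{rid}@{sig}" for rid, sig in cand.applied_rules) or "-"
                    candidate_rows.append(
                        (
                            rset.rank,
                            f"{backbone_id}_m{mi}",
                            cand.smiles,
                            cand.monoisotopic_mass,
                            applied,
                        )
                    )
    report["stages"]["selection"] = {"n_ranked_sets": n_sets_total}
    report["stages"]["assembly"] = {"n_backbones": n_backbones_total}
    report["stages"]["modification"] = {"n_mature_candidates": n_mature_total}

    candidates_csv = out_dir / "candidates.csv"
    lines = ["set_rank,backbone_id,smiles,monoisotopic_mass,applied_rules"]
    for rank, cid, smiles, mass, applied in candidate_rows:
        lines.append(f"{rank},{cid},{smiles},{mass:.5f},{applied}")
    candidates_csv.write_text("\n".join(lines) + "\n")

    # stage 6: spectral search -------------------------------------------
    if spectra_mgf is not None:
        spectra = spectral_matching.read_mgf(spectra_mgf)
        triples = [(cid, smiles, mass) for _r, cid, smiles, mass, _a in candidate_rows]
        # deduplicate identical structures across backbones (keep first id)
        seen: set[str] = set()
        unique_triples = []
        for cid, smiles, mass in triples:
            if smiles in seen:
                continue
            seen.add(smiles)
            unique_triples.append((cid, smiles, mass))
        results = spectral_matching.search(unique_triples, spectra, config.search_config())
        smiles_by_id = {cid: smiles for cid, smiles, _m in unique_triples}
        (out_dir / "matches.tsv").write_text(
            spectral_matching.results_to_tsv(results, smiles_by_id)
        )
        report["stages"]["search"] = {
            "n_spectra": len(spectra),
            "n_candidates_searched": len(unique_triples),
            "n_matches": len(results),
        }

    _write_report(out_dir, report)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _write_report(out_dir: Path, report: dict) -> None:
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# benchmarking
# ---------------------------------------------------------------------------


def _fingerprint_bits(smiles: str, max_path: int = 7, fp_size: int = 2048) -> frozenset[int]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=max_path, fpSize=fp_size)
    return frozenset(gen.GetFingerprint(mol).GetOnBits())


def tanimoto(smiles_a: str, smiles_b: str, max_path: int = 7, fp_size: int = 2048) -> float:
    """Tanimoto similarity over binary path-based substructure features:
    |F(a) & F(b)| / |F(a) | F(b)|.

    Path features up to ``max_path`` bonds; the value depends on the
    fingerprint choice, which is therefore part of the reported config.
    Identical canonical graphs give 1.0, feature-disjoint molecules 0.0.
    """
    fa = _fingerprint_bits(smiles_a, max_path, fp_size)
    fb = _fingerprint_bits(smiles_b, max_path, fp_size)
    if not fa and not fb:
        return 1.0
    union = fa | fb
    if not union:
        return 0.0
    return len(fa & fb) / len(union)


DEFAULT_THRESHOLDS = (0.7, 0.85, 0.95, 1.0)


def benchmark_report(
    predictions: dict[str, Sequence[str]],
    truths: dict[str, str],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict:
    """Count correctly predicted structures at Tanimoto thresholds.

    ``predictions`` maps molecule name -> candidate SMILES collection;
    ``truths`` maps molecule name -> true SMILES.  Empty candidate sets
    score a best similarity of 0.  Returns per-molecule best similarities
    and per-threshold counts (non-increasing in the threshold).
    """
    per_molecule = {}
    for name, truth_smiles in sorted(truths.items()):
        candidates = predictions.get(name, [])
        best = 0.0
        for cand in candidates:
            best = max(best, tanimoto(cand, truth_smiles))
            if best == 1.0:
                break
        per_molecule[name] = best
    counts = {
        threshold: sum(1 for v in per_molecule.values() if v >= threshold)
        for threshold in thresholds
    }
    return {"best_similarity": per_molecule, "counts": counts}
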