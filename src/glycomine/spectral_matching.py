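"""In-silico fragmentation and tandem-MS candidate matching.

This is a deliberately simple, fully specified scorer.  Theoretical spectra
are produced by cleaving up to ``max_cuts`` bridge bonds between monomer
units (acyclic bonds whose removal leaves two sufficiently large pieces) and
recording neutral connected-component masses.  An experimental spectrum is
scored by the shared-peak count: greedy one-to-one nearest-mass matching of
experimental peaks to adduct-adjusted fragment m/z values within a tolerance.
The variable (mass-shift-tolerant) mode maximizes that score over one global
shift applied to the fragments on a designated side of a cut, which absorbs a
missing terminal monomer or modification; shift zero is always included, so
the variable score never falls below the standard score.  Significance is an
empirical decoy p-value: fragment masses are resampled uniformly over the
theoretical spectrum's mass range, preserving the fragment count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .knowledge_base import MONOISOTOPIC

logger = logging.getLogger(__name__)

PROTON_MASS = 1.00727646688

#: adduct label -> m/z offset from the neutral monoisotopic mass (charge 1).
#: [M+NH3]- models an ammonia adduct observed after deprotonation, the
#: negative-mode analyte form reported for trestatin-class oligosaccharides.
ADDUCTS = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    "[M+NH3]-": 3 * MONOISOTOPIC["H"] + MONOISOTOPIC["N"] - PROTON_MASS,
}

DEFAULT_FRAGMENT_TOL_DA = 0.01
DEFAULT_PRECURSOR_TOL_PPM = 10.0
DEFAULT_PVALUE_THRESHOLD = 1e-3
MIN_BRIDGE_COMPONENT_ATOMS = 4  # heavy atoms per side for a bond to count as a bridge


@dataclass(frozen=True)
class ExperimentalSpectrum:
    spectrum_id: str
    precursor_mz: float
    charge: int
    peaks: tuple[tuple[float, float], ...]  # (mz, intensity), sorted by mz
    adducts: tuple[str, ...] = ("[M+H]+",)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.spectrum_id}: nonpositive precursor m/z")
        mzs = [mz for mz, _ in self.peaks]
        if any(mz <= 0 for mz in mzs):
            raise ValueError(f"{self.spectrum_id}: nonpositive peak m/z")
        if list(mzs) != sorted(mzs):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))

    def neutral_mass(self, adduct: str) -> float:
        if adduct not in ADDUCTS:
            raise ValueError(f"unknown adduct label {adduct!r}")
        return self.precursor_mz - ADDUCTS[adduct]


@dataclass(frozen=True)
class Fragment:
    mass: float  # neutral fragment mass, Da
    n_cuts: int
    composition: str  # elemental formula key used for deduplication


@dataclass(frozen=True)
class TheoreticalSpectrum:
    candidate_id: str
    intact_mass: float
    fragments: tuple[Fragment, ...]

    @property
    def masses(self) -> np.ndarray:
        return np.array([f.mass for f in self.fragments])


@dataclass(frozen=True)
class MatchResult:
    candidate_id: str
    spectrum_id: str
    score: int
    shift: float
    p_value: float
    adduct: str = "[M+H]+"


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------


def bridge_bonds(mol: Chem.Mol) -> list[int]:
    """Bond indices treated as inter-monomer bridges.

    A bridge is an acyclic single bond between heavy atoms whose cleavage
    leaves at least :data:`MIN_BRIDGE_COMPONENT_ATOMS` heavy atoms on each
    side, so peripheral hydroxyl/methyl bonds are not fragmented while
    glycosidic (C-O-C), N-glycosidic and amide linkers are.
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(a.GetIdx() for a in mol.GetAtoms())
    for bond in mol.GetBonds():
        graph.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    bridges = []
    for bond in mol.GetBonds():
        if bond.IsInRing():
            continue
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        graph.remove_edge(u, v)
        side_u = nx.node_connected_component(graph, u)
        side_v = nx.node_connected_component(graph, v)
        graph.add_edge(u, v)
        if len(side_u) >= MIN_BRIDGE_COMPONENT_ATOMS and len(side_v) >= MIN_BRIDGE_COMPONENT_ATOMS:
            bridges.append(bond.GetIdx())
    return bridges


def _atom_mass(atom: Chem.Atom) -> float:
    return MONOISOTOPIC[atom.GetSymbol()] + atom.GetTotalNumHs() * MONOISOTOPIC["H"]


def fragment(
    structure: str | Chem.Mol,
    max_cuts: int = 2,
    candidate_id: str = "candidate",
) -> TheoreticalSpectrum:
    """Enumerate neutral fragments over all subsets of <= ``max_cuts`` bridges.

    The zero-cut subset contributes the intact molecule, so the intact mass
    is always present; fragments are deduplicated by (mass, composition) and
    hydrogens broken bonds would redistribute are kept with their parent
    atoms (homolytic bookkeeping).
    """
    import networkx as nx

    mol = Chem.MolFromSmiles(structure) if isinstance(structure, str) else structure
    if mol is None:
        raise ValueError("unparseable structure for fragmentation")
    bridges = bridge_bonds(mol)

    graph = nx.Graph()
    graph.add_nodes_from(a.GetIdx() for a in mol.GetAtoms())
    for bond in mol.GetBonds():
        graph.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), idx=bond.GetIdx())

    atom_masses = {a.GetIdx(): _atom_mass(a) for a in mol.GetAtoms()}
    atom_symbols = {a.GetIdx(): (a.GetSymbol(), a.GetTotalNumHs()) for a in mol.GetAtoms()}
    intact_mass = sum(atom_masses.values())

    seen: dict[tuple[int, str], Fragment] = {}
    for n_cuts in range(0, min(max_cuts, len(bridges)) + 1):
        for subset in itertools.combinations(bridges, n_cuts):
            cut = set(subset)
            sub = nx.Graph()
            sub.add_nodes_from(graph.nodes)
            for u, v, data in graph.edges(data=True):
                if data["idx"] not in cut:
                    sub.add_edge(u, v)
            for component in nx.connected_components(sub):
                mass = sum(atom_masses[i] for i in component)
                counts: dict[str, int] = {}
                for i in component:
                    sym, nh = atom_symbols[i]
                    counts[sym] = counts.get(sym, 0) + 1
                    counts["H"] = counts.get("H", 0) + nh
                composition = "".join(f"{s}{counts[s]}" for s in sorted(counts))
                key = (round(mass * 1e6), composition)
                if key not in seen:
                    seen[key] = Fragment(mass=mass, n_cuts=n_cuts, composition=composition)
    fragments = tuple(sorted(seen.values(), key=lambda f: (f.mass, f.composition)))
    return TheoreticalSpectrum(
        candidate_id=candidate_id, intact_mass=intact_mass, fragments=fragments
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _greedy_match_count(peaks: np.ndarray, frag_mz: np.ndarray, tol: float) -> int:
    """Greedy one-to-one nearest-mass matching; returns matched-peak count."""
    if peaks.size == 0 or frag_mz.size == 0:
        return 0
    order = np.argsort(frag_mz)
    frag_sorted = frag_mz[order]
    pairs: list[tuple[float, int, int]] = []
    for pi, mz in enumerate(peaks):
        lo = np.searchsorted(frag_sorted, mz - tol)
        hi = np.searchsorted(frag_sorted, mz + tol, side="right")
        for fi in range(lo, hi):
            pairs.append((abs(frag_sorted[fi] - mz), pi, fi))
    pairs.sort()
    used_peaks: set[int] = set()
    used_frags: set[int] = set()
    count = 0
    for _dist, pi, fi in pairs:
        if pi in used_peaks or fi in used_frags:
            continue
        used_peaks.add(pi)
        used_frags.add(fi)
        count += 1
    return count


def _fragment_mzs(theo: TheoreticalSpectrum, adduct: str, shift: float = 0.0) -> np.ndarray:
    """Adduct-adjusted fragment m/z values, optionally with the sub-molecule
    shift applied to the complementary copies.

    A global shift of the molecule (missing monomer / unknown modification)
    moves the fragments that contain the altered portion while the fragments
    on the other side of the cut keep their mass; since the altered side is
    unknown, each fragment is offered both unshifted and shifted."""
    if adduct not in ADDUCTS:
        raise ValueError(f"unknown adduct label {adduct!r}")
    base = np.array([f.mass + ADDUCTS[adduct] for f in theo.fragments])
    if shift == 0.0:
        return base
    return np.concatenate([base, base + shift])


def score_match(
    theo: TheoreticalSpectrum,
    exp: ExperimentalSpectrum,
    tol: float = DEFAULT_FRAGMENT_TOL_DA,
    adduct: str = "[M+H]+",
    intensity_weighted: bool = False,
) -> int | float:
    """Shared-peak count: experimental peaks matched one-to-one by any
    adduct-adjusted theoretical fragment within ``tol`` Da.

    With ``intensity_weighted`` the matched peaks' total relative intensity
    (fraction of the spectrum's summed intensity) is returned instead of the
    integer count."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    peaks = np.array([mz for mz, _ in exp.peaks])
    if not intensity_weighted:
        return _greedy_match_count(peaks, _fragment_mzs(theo, adduct), tol)
    frag_mz = np.sort(_fragment_mzs(theo, adduct))
    total = sum(intensity for _mz, intensity in exp.peaks) or 1.0
    matched = 0.0
    for mz, intensity in exp.peaks:
        lo = np.searchsorted(frag_mz, mz - tol)
        hi = np.searchsorted(frag_mz, mz + tol, side="right")
        if hi > lo:
            matched += intensity
    return matched / total


def variable_score(
    theo: TheoreticalSpectrum,
    exp: ExperimentalSpectrum,
    tol: float = DEFAULT_FRAGMENT_TOL_DA,
    adduct: str = "[M+H]+",
    shift_bounds: tuple[float, float] = (-500.0, 500.0),
    shift_grid: Sequence[float] | None = None,
) -> tuple[int, float]:
    """Best (score, shift) over candidate global mass shifts.

    Candidate shifts are zero, the precursor-vs-intact mass difference, and
    any user grid, restricted to ``shift_bounds``.  With bounds (0, 0) the
    search degenerates to :func:`score_match` exactly.
    """
    lo, hi = shift_bounds
    candidates = {0.0}
    observed = exp.neutral_mass(adduct) - theo.intact_mass
    for s in ([observed] if shift_grid is None else list(shift_grid) + [observed]):
        if lo <= s <= hi and abs(s) > tol:
            candidates.add(float(s))
    peaks = np.array([mz for mz, _ in exp.peaks])
    best_score, best_shift = -1, 0.0
    for s in sorted(candidates):
        score = _greedy_match_count(peaks, _fragment_mzs(theo, adduct, s), tol)
        if score > best_score or (score == best_score and abs(s) < abs(best_shift)):
            best_score, best_shift = score, s
    return best_score, best_shift


# ---------------------------------------------------------------------------
# empirical significance
# ---------------------------------------------------------------------------


def empirical_pvalue(
    observed_score: int,
    theo: TheoreticalSpectrum,
    exp: ExperimentalSpectrum,
    tol: float = DEFAULT_FRAGMENT_TOL_DA,
    adduct: str = "[M+H]+",
    n_decoys: int = 999,
    rng: np.random.Generator | None = None,
    variable: bool = False,
    shift_bounds: tuple[float, float] = (-500.0, 500.0),
) -> float:
    """Decoy-based p-value: ``(1 + #{decoys >= observed}) / (n_decoys + 1)``.

    Decoy theoretical spectra resample fragment masses uniformly over the
    real spectrum's fragment mass range, preserving the fragment count.
    """
    if n_decoys < 99:
        raise ValueError("at least 99 decoys required for a meaningful p-value")
    rng = rng or np.random.default_rng(0)
    masses = theo.masses
    lo, hi = float(masses.min()), float(masses.max())
    peaks = np.array([mz for mz, _ in exp.peaks])
    exceed = 0
    for _ in range(n_decoys):
        decoy_masses = rng.uniform(lo, hi, size=masses.size)
        decoy = TheoreticalSpectrum(
            candidate_id="decoy",
            intact_mass=theo.intact_mass,
            fragments=tuple(
                Fragment(mass=float(m), n_cuts=0, composition="") for m in np.sort(decoy_masses)
            ),
        )
        if variable:
            score, _ = variable_score(decoy, exp, tol, adduct, shift_bounds)
        else:
            score = _greedy_match_count(peaks, _fragment_mzs(decoy, adduct), tol)
        if score >= observed_score:
            exceed += 1
    return (1 + exceed) / (n_decoys + 1)


# ---------------------------------------------------------------------------
# spectra IO and the search driver
# ---------------------------------------------------------------------------


def read_mgf(path: str | Path) -> list[ExperimentalSpectrum]:
    from pyteomics import mgf

    spectra = []
    with mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"spectrum_{i}"))
            pepmass = params.get("pepmass", (0.0,))
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = 1
            if "charge" in params:
                charge_val = params["charge"]
                charge = int(charge_val[0]) if isinstance(charge_val, (list, tuple)) else int(charge_val)
            peaks = tuple(
                (float(mz), float(it))
                for mz, it in zip(entry["m/z array"], entry["intensity array"])
            )
            spectra.append(
                ExperimentalSpectrum(
                    spectrum_id=title,
                    precursor_mz=precursor,
                    charge=charge,
                    peaks=tuple(sorted(peaks)),
                )
            )
    return spectra


def read_mzml(path: str | Path) -> list[ExperimentalSpectrum]:
    from pyteomics import mzml

    spectra = []
    with mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            precursor = entry["precursorList"]["precursor"][0]
            ion = precursor["selectedIonList"]["selectedIon"][0]
            peaks = tuple(
                (float(mz), float(it))
                for mz, it in zip(entry["m/z array"], entry["intensity array"])
            )
            spectra.append(
                ExperimentalSpectrum(
                    spectrum_id=entry.get("id", "scan"),
                    precursor_mz=float(ion["selected ion m/z"]),
                    charge=int(ion.get("charge state", 1)),
                    peaks=tuple(sorted(peaks)),
                )
            )
    return spectra


@dataclass
class SearchConfig:
    fragment_tol_da: float = DEFAULT_FRAGMENT_TOL_DA
    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM
    adducts: tuple[str, ...] = ("[M+H]+", "[M-H]-", "[M+NH3]-")
    max_cuts: int = 2
    n_decoys: int = 999
    p_value_threshold: float = DEFAULT_PVALUE_THRESHOLD
    variable: bool = False
    shift_bounds: tuple[float, float] = (-500.0, 500.0)
    seed: int = 0
    report_all: bool = False  # keep matches above the p-value threshold too


def search(
    candidates: Sequence[tuple[str, str, float]],
    spectra: Sequence[ExperimentalSpectrum],
    config: SearchConfig | None = None,
) -> list[MatchResult]:
    """Match candidate structures against experimental spectra.

    ``candidates`` rows are (candidate_id, smiles, neutral monoisotopic
    mass).  For each spectrum, candidates passing the precursor filter (mass
    within the ppm tolerance under some adduct, or within the shift bounds in
    variable mode) are fragmented, scored, and assigned decoy p-values; rows
    at or below the threshold are returned (all rows with ``report_all``).
    Deterministic for a fixed config: the decoy RNG is seeded per
    (spectrum, candidate) from ``config.seed``.
    """
    config = config or SearchConfig()
    theo_cache: dict[str, TheoreticalSpectrum] = {}
    results: list[MatchResult] = []

    for spectrum in spectra:
        for cand_id, smiles, mass in candidates:
            for adduct in config.adducts:
                neutral = spectrum.neutral_mass(adduct)
                delta = neutral - mass
                ppm = abs(delta) / max(mass, 1e-9) * 1e6
                if config.variable:
                    lo, hi = config.shift_bounds
                    if not (lo <= delta <= hi or ppm <= config.precursor_tol_ppm):
                        continue
                elif ppm > config.precursor_tol_ppm:
                    continue
                if cand_id not in theo_cache:
                    theo_cache[cand_id] = fragment(
                        smiles, max_cuts=config.max_cuts, candidate_id=cand_id
                    )
                theo = theo_cache[cand_id]
                if config.variable:
                    score, shift = variable_score(
                        theo,
                        spectrum,
                        config.fragment_tol_da,
                        adduct,
                        config.shift_bounds,
                    )
                else:
                    score = score_match(theo, spectrum, config.fragment_tol_da, adduct)
                    shift = 0.0
                if score == 0:
                    continue
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [config.seed, _stable_hash(spectrum.spectrum_id), _stable_hash(cand_id)]
                    )
                )
                p = empirical_pvalue(
                    score,
                    theo,
                    spectrum,
                    config.fragment_tol_da,
                    adduct,
                    config.n_decoys,
                    rng,
                    variable=config.variable,
                    shift_bounds=config.shift_bounds,
                )
                if config.report_all or p <= config.p_value_threshold:
                    results.append(
                        MatchResult(
                            candidate_id=cand_id,
                            spectrum_id=spectrum.spectrum_id,
                            score=score,
                            shift=shift,
                            p_value=p,
                            adduct=adduct,
                        )
                    )
    results.sort(key=lambda r: (r.spectrum_id, r.p_value, -r.score, r.candidate_id))
    return results


def _stable_hash(text: str) -> int:
    """Deterministic 31-bit hash (process-seed independent)."""
    value = 0
    for ch in text:
        value = (value * 131 + ord(ch)) % 2147483647
    return value


def results_to_tsv(
    results: Sequence[MatchResult], smiles_by_id: dict[str, str] | None = None
) -> str:
    smiles_by_id = smiles_by_id or {}
    header = "spectrum_id\tcandidate_id\tsmiles\tadduct\tshift\tscore\tp_value"
    lines = [header]
    for r in results:
        lines.append(
            f"{r.spectrum_id}\t{r.candidate_id}\t{smiles_by_id.get(r.candidate_id, '-')}\t"
            f"{r.adduct}\t{r.shift:.4f}\t{r.score}\t{r.p_value:.6g}"
        )
    return "\n".join(lines) + "\n"
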