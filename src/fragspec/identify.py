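"""Candidate ranking: score observed spectra against predicted spectra of
candidate structures and rank by the Jaccard score averaged over the
provided collision energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .chem import (
    AdductSpec,
    ChemError,
    MoleculeStructure,
    monoisotopic_mass,
    parse_structure,
)
from .fraggraph import DEFAULT_MAX_DEPTH, GraphError
from .model import DEFAULT_PRUNE_THRESHOLD, TransitionModel
from .predict import predict_single_energy
from .spectra import ENERGY_LEVELS, Spectrum
from .tolerance import MassTolerance

MAX_CANDIDATES = 100


@dataclass
class CandidateRecord:
    ref_id: str
    smiles: str
    neutral_mass: float | None = None
    mol: MoleculeStructure | None = None
    parse_failed: bool = False

    @classmethod
    def from_line(cls, ref_id: str, smiles: str) -> "CandidateRecord":
        try:
            mol = parse_structure(smiles)
        except ChemError:
            return cls(ref_id, smiles, parse_failed=True)
        return cls(ref_id, smiles, monoisotopic_mass(mol), mol)


@dataclass
class PrecursorQuery:
    """Precursor-mass filter: m/z, tolerance (absolute Da or ppm), and the
    adducts considered when back-computing candidate neutral masses."""

    precursor_mz: float
    adducts: list[AdductSpec]
    tol_da: float | None = None
    tol_ppm: float | None = None

    def __post_init__(self) -> None:
        if (self.tol_da is None) == (self.tol_ppm is None):
            raise ValueError("specify exactly one of tol_da / tol_ppm")
        tol = self.tol_da if self.tol_da is not None else self.tol_ppm
        if tol is None or tol <= 0:
            raise ValueError("tolerance must be positive")

    def window(self) -> float:
        if self.tol_da is not None:
            return self.tol_da
        return self.tol_ppm * self.precursor_mz * 1e-6


@dataclass
class CandidateScore:
    ref_id: str
    smiles: str
    score: float
    rank: int
    parse_failed: bool = False


def filter_candidates(candidates: list[CandidateRecord],
                      query: PrecursorQuery) -> list[CandidateRecord]:
    """Keep candidates whose neutral mass plus some listed adduct delta
    falls within the precursor window; input order is preserved."""
    window = query.window()
    kept = []
    for cand in candidates:
        if cand.neutral_mass is None:
            continue
        for adduct in query.adducts:
            if abs(cand.neutral_mass + adduct.mass_delta
                   - query.precursor_mz) <= window:
                kept.append(cand)
                break
    return kept


def jaccard_score(predicted: Spectrum, observed: Spectrum,
                  tol: MassTolerance) -> float:
    """Set Jaccard between two peak lists under a mass tolerance.

    Peaks are paired greedily, closest mass difference first, each peak
    used at most once; score = matches / (|predicted| + |observed| -
    matches). Intensities are ignored. Symmetric in its two arguments.
    """
    if not predicted.peaks or not observed.peaks:
        raise ValueError("jaccard_score requires non-empty spectra")
    a = predicted.mz
    b = observed.mz
    pairs = []
    for i, ma in enumerate(a):
        for j, mb in enumerate(b):
            if abs(ma - mb) <= max(tol.window(ma), tol.window(mb)):
                key = (abs(ma - mb), min(ma, mb), max(ma, mb))
                pairs.append((key, i, j))
    pairs.sort(key=lambda p: p[0])
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = 0
    for _key, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches += 1
    return matches / (len(a) + len(b) - matches)


def weighted_jaccard_score(predicted: Spectrum, observed: Spectrum,
                           tol: MassTolerance) -> float:
    """Intensity-weighted variant: matched peaks contribute the mean of
    their normalized intensities; non-default, exposed behind a flag."""
    if not predicted.peaks or not observed.peaks:
        raise ValueError("weighted_jaccard_score requires non-empty spectra")
    pa = predicted.base_normalized()
    pb = observed.base_normalized()
    wa = {i: p.intensity for i, p in enumerate(pa.peaks)}
    wb = {j: p.intensity for j, p in enumerate(pb.peaks)}
    pairs = []
    for i, p in enumerate(pa.peaks):
        for j, q in enumerate(pb.peaks):
            if abs(p.mz - q.mz) <= max(tol.window(p.mz), tol.window(q.mz)):
                key = (abs(p.mz - q.mz), min(p.mz, q.mz), max(p.mz, q.mz))
                pairs.append((key, i, j))
    pairs.sort(key=lambda x: x[0])
    used_a: set[int] = set()
    used_b: set[int] = set()
    inter = 0.0
    for _key, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        inter += 0.5 * (wa[i] + wb[j])
    union = sum(wa.values()) + sum(wb.values()) - inter
    return inter / union if union > 0 else 0.0


def identify(query_spectra: dict[str, Spectrum],
             candidates: list[CandidateRecord],
             mode: str,
             models: dict[str, TransitionModel],
             tol: MassTolerance,
             top_k: int | None = None,
             weighted: bool = False,
             prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
             max_depth: int = DEFAULT_MAX_DEPTH) -> list[CandidateScore]:
    """Rank candidates against 1-3 observed spectra.

    Per candidate, spectra are predicted at each provided energy and the
    (set or intensity-weighted) Jaccard score is averaged over energies.
    Ties rank by ascending reference id. Unparsable candidates score 0
    with a warning rather than aborting the run.
    """
    if not query_spectra:
        raise ValueError("at least one query spectrum is required")
    if len(candidates) > MAX_CANDIDATES:
        raise ValueError(
            f"candidate list has {len(candidates)} entries; at most "
            f"{MAX_CANDIDATES} candidates are allowed")
    energies = [e for e in ENERGY_LEVELS if e in query_spectra]
    scorer = weighted_jaccard_score if weighted else jaccard_score
    scored: list[tuple[float, str, CandidateRecord]] = []
    for cand in candidates:
        if cand.parse_failed or cand.mol is None:
            warnings.warn(f"candidate {cand.ref_id}: unparsable SMILES, scored 0")
            scored.append((0.0, cand.ref_id, cand))
            continue
        try:
            total = 0.0
            for energy in energies:
                pred = predict_single_energy(
                    cand.mol, mode, models[energy],
                    prune_threshold=prune_threshold, max_depth=max_depth)
                total += scorer(pred, query_spectra[energy], tol)
            scored.append((total / len(energies), cand.ref_id, cand))
        except GraphError:
            warnings.warn(f"candidate {cand.ref_id}: enumeration exceeded the "
                          f"node cap, scored 0")
            scored.append((0.0, cand.ref_id, cand))
    scored.sort(key=lambda s: (-s[0], s[1]))
    out = [
        CandidateScore(c.ref_id, c.smiles, score, rank, c.parse_failed)
        for rank, (score, _rid, c) in enumerate(scored, start=1)
    ]
    return out[:top_k] if top_k is not None else out
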