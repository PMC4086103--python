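"""Peak assignment: explain observed peaks with enumerated fragments.

Every fragment whose ion mass lies within the mass tolerance of a peak
becomes a candidate annotation for it. Candidates are ordered by the
model's marginal probability, and each carries an explained-intensity
score: the share of the peak intensity attributed to that fragment,
splitting the intensity across candidates in proportion to their
marginals. The union of all matched fragments (plus their root paths)
forms the pruned fragmentation graph reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import (
    PROTONATION,
    AdductSpec,
    ChemError,
    MoleculeStructure,
    precursor_mz,
)
from .fraggraph import DEFAULT_MAX_DEPTH, FragmentationGraph, build_graph, prune_graph
from .model import TransitionModel, marginals
from .spectra import ENERGY_LEVELS, Peak, Spectrum
from .tolerance import MassTolerance


@dataclass
class PeakAssignment:
    """Candidate fragments for one observed peak, ordered from most to
    least likely; score = explained share of the peak intensity."""

    peak: Peak
    candidates: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class AnnotationResult:
    assignments: dict[str, list[PeakAssignment]]  # energy -> per-peak
    pruned_graph: FragmentationGraph
    mol: MoleculeStructure


def match_fragments(spectrum: Spectrum, graph: FragmentationGraph,
                    model: TransitionModel, tol: MassTolerance,
                    adduct: AdductSpec | None = None,
                    mol: MoleculeStructure | None = None,
                    ) -> list[PeakAssignment]:
    """Assign every tolerance-matched fragment to every peak.

    When a non-protonation ``adduct`` is given, the precursor node (only)
    is additionally matched at the adduct mass; daughter ions are always
    matched at their [M+H]+ / [M-H]- masses.
    """
    marg = marginals(model, graph)
    adduct_mz = None
    if adduct is not None and mol is not None \
            and adduct.name != PROTONATION[graph.mode].name:
        if adduct.polarity != graph.mode:
            raise ChemError(f"adduct {adduct.name} does not fit mode {graph.mode}")
        adduct_mz = precursor_mz(mol, adduct)
    assignments = []
    for peak in spectrum.peaks:
        hits = [n.id for n in graph.nodes if tol.matches(peak.mz, n.ion_mass)]
        if adduct_mz is not None and tol.matches(peak.mz, adduct_mz) and 0 not in hits:
            hits.append(0)
        total = sum(marg[h] for h in hits)
        cands = []
        for h in hits:
            share = (marg[h] / total) if total > 0 else 1.0 / len(hits)
            cands.append((h, peak.intensity * share))
        cands.sort(key=lambda c: (-marg[c[0]], c[0]))
        assignments.append(PeakAssignment(peak, cands))
    return assignments


def annotate(spectra: dict[str, Spectrum], mol: MoleculeStructure, mode: str,
             tol: MassTolerance, models: dict[str, TransitionModel],
             adduct: AdductSpec | None = None,
             max_depth: int = DEFAULT_MAX_DEPTH) -> AnnotationResult:
    """Annotate one to three observed spectra of a known structure.

    Each provided energy is matched with its own single-energy model; no
    imputation is attempted for missing energies. The pruned graph is
    induced by the union of matched fragment ids across energies.
    """
    if not spectra:
        raise ValueError("at least one spectrum is required")
    unknown = set(spectra) - set(ENERGY_LEVELS)
    if unknown:
        raise ValueError(f"unknown energy levels: {sorted(unknown)}")
    graph = build_graph(mol, mode, max_depth=max_depth)
    assignments: dict[str, list[PeakAssignment]] = {}
    matched_ids: set[int] = set()
    for energy in ENERGY_LEVELS:
        if energy not in spectra:
            continue
        if energy not in models:
            raise ValueError(f"no model supplied for energy {energy!r}")
        per_peak = match_fragments(spectra[energy], graph, models[energy],
                                   tol, adduct=adduct, mol=mol)
        assignments[energy] = per_peak
        for pa in per_peak:
            matched_ids.update(fid for fid, _ in pa.candidates)
    pruned = prune_graph(graph, matched_ids)
    return AnnotationResult(assignments=assignments, pruned_graph=pruned, mol=mol)
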