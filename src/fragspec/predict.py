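"""Spectrum prediction: structure in, low/medium/high-energy peak lists out.

Pipeline per energy: build the fragmentation graph, compute terminal
marginals with probability pruning, pool node probabilities into peaks,
apply the display selection rule (top 80% of total intensity, between 5
and 30 peaks), and append the extra precursor peak when a non-protonation
adduct is selected.
"""

from __future__ import annotations

from .chem import (
    NEGATIVE,
    POSITIVE,
    PROTONATION,
    AdductSpec,
    ChemError,
    MoleculeStructure,
    precursor_mz,
)
from .fraggraph import DEFAULT_MAX_DEPTH, FragmentationGraph, build_graph
from .model import (
    DEFAULT_PRUNE_THRESHOLD,
    TransitionModel,
    marginals,
    prune_by_probability,
)
from .spectra import ENERGY_LEVELS, Peak, Spectrum

#: Nodes whose enumerated masses coincide within this window pool into one
#: peak. These are computed (not measured) masses, so only exact-mass
#: collisions should merge.
PEAK_MERGE_TOL = 1e-5

#: Display selection constants: retain the smallest high-intensity prefix
#: reaching this fraction of the total, then clamp the peak count.
SELECT_FRACTION = 0.80
SELECT_MIN_PEAKS = 5
SELECT_MAX_PEAKS = 30


def raw_spectrum(marginal: dict[int, float], graph: FragmentationGraph,
                 energy_level: str = "medium") -> Spectrum:
    """Unselected predicted spectrum: marginal probability mass pooled by
    ion mass, rescaled to base peak 100, annotated with contributing
    fragment ids ordered by probability share."""
    nodes = sorted(graph.nodes, key=lambda n: n.ion_mass)
    groups: list[list] = []
    for n in nodes:
        if groups and abs(n.ion_mass - groups[-1][0].ion_mass) <= PEAK_MERGE_TOL:
            groups[-1].append(n)
        else:
            groups.append([n])
    peaks = []
    for grp in groups:
        total = sum(marginal.get(n.id, 0.0) for n in grp)
        if total <= 0:
            continue
        ann = sorted(((n.id, marginal.get(n.id, 0.0)) for n in grp),
                     key=lambda kv: (-kv[1], kv[0]))
        mz = sum(n.ion_mass * marginal.get(n.id, 0.0) for n in grp) / total
        peaks.append(Peak(mz, total, ann))
    return Spectrum(energy_level, peaks).base_normalized()


def select_peaks(spectrum: Spectrum) -> Spectrum:
    """Display selection: smallest descending-intensity prefix holding at
    least 80% of the total intensity, count clamped into [5, 30] (never
    more than available), re-sorted by m/z, renormalized to base 100.
    Intensity ties break by ascending m/z for determinism."""
    if not spectrum.peaks:
        raise ValueError("cannot select peaks of an empty spectrum")
    ranked = sorted(spectrum.peaks, key=lambda p: (-p.intensity, p.mz))
    total = sum(p.intensity for p in ranked)
    cum = 0.0
    k = 0
    for p in ranked:
        cum += p.intensity
        k += 1
        if cum >= SELECT_FRACTION * total:
            break
    k = max(k, SELECT_MIN_PEAKS)
    k = min(k, SELECT_MAX_PEAKS, len(ranked))
    kept = ranked[:k]
    return Spectrum(spectrum.energy_level,
                    [Peak(p.mz, p.intensity, list(p.annotations)) for p in kept]
                    ).base_normalized()


def add_adduct_peak(spectrum: Spectrum, mol: MoleculeStructure,
                    adduct: AdductSpec, mode: str,
                    precursor_intensity: float | None = None) -> Spectrum:
    """Append the extra peak at the precursor adduct mass.

    The fragmentation model cannot predict an intensity for adduct ions,
    so the peak copies the protonated/deprotonated precursor intensity.
    ``precursor_intensity`` supplies the pre-selection value when the
    precursor peak did not survive selection. Plain [M+H]+ / [M-H]- is an
    identity operation; adducts never propagate to daughter ions.
    """
    if adduct.polarity != mode:
        raise ChemError(f"adduct {adduct.name} is not a {mode}-mode adduct")
    if adduct.name == PROTONATION[mode].name:
        return spectrum
    base_mz = precursor_mz(mol, PROTONATION[mode])
    intensity = None
    for p in spectrum.peaks:
        if abs(p.mz - base_mz) <= PEAK_MERGE_TOL:
            intensity = p.intensity
            break
    if intensity is None:
        intensity = precursor_intensity
    if intensity is None:
        raise ValueError("precursor peak absent and no pre-selection "
                         "intensity supplied")
    adduct_mz = precursor_mz(mol, adduct)
    peaks = [Peak(p.mz, p.intensity, list(p.annotations)) for p in spectrum.peaks]
    peaks.append(Peak(adduct_mz, intensity, [(0, intensity)]))
    return Spectrum(spectrum.energy_level, peaks)


def predict_single_energy(mol: MoleculeStructure, mode: str,
                          model: TransitionModel,
                          adduct: AdductSpec | None = None,
                          graph: FragmentationGraph | None = None,
                          prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
                          max_depth: int = DEFAULT_MAX_DEPTH,
                          select: bool = True) -> Spectrum:
    """Predicted spectrum at one collision energy."""
    if graph is None:
        graph = build_graph(mol, mode, max_depth=max_depth)
    pruned = prune_by_probability(graph, model, prune_threshold)
    marg = marginals(model, pruned)
    raw = raw_spectrum(marg, pruned, model.energy_level)
    out = select_peaks(raw) if select else raw
    if adduct is not None and adduct.name != PROTONATION[mode].name:
        base_mz = precursor_mz(mol, PROTONATION[mode])
        pre = next((p.intensity for p in raw.peaks
                    if abs(p.mz - base_mz) <= PEAK_MERGE_TOL), 0.0)
        out = add_adduct_peak(out, mol, adduct, mode, precursor_intensity=pre)
    return out


def predict(mol: MoleculeStructure, mode: str,
            models: dict[str, TransitionModel],
            adduct: AdductSpec | None = None,
            prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
            max_depth: int = DEFAULT_MAX_DEPTH,
            select: bool = True) -> dict[str, Spectrum]:
    """Predict all three collision-energy spectra for a neutral molecule.

    ``models`` maps each of "low"/"medium"/"high" to its trained
    single-energy model. The fragmentation graph is built once and shared.
    Deterministic for fixed model parameters.
    """
    if mode not in (POSITIVE, NEGATIVE):
        raise ChemError(f"unknown ionization mode {mode!r}")
    missing = [e for e in ENERGY_LEVELS if e not in models]
    if missing:
        raise ValueError(f"missing models for energies: {missing}")
    graph = build_graph(mol, mode, max_depth=max_depth)
    out: dict[str, Spectrum] = {}
    for energy in ENERGY_LEVELS:
        model = models[energy]
        if model.energy_level != energy:
            raise ValueError(f"model for {energy!r} is tagged {model.energy_level!r}")
        out[energy] = predict_single_energy(
            mol, mode, model, adduct=adduct, graph=graph,
            prune_threshold=prune_threshold, select=select)
    return out
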