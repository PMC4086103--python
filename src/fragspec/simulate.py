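"""Synthetic molecules and model-sampled spectra.

The generator makes every part of the toolkit testable without external
data: a reproducible library of small, valence-legal molecules (random
heavy-atom trees plus occasional single rings, hydrogen-filled), a fixed
set of reference transition-model parameters playing the role of a
"true" fragmentation chemistry, and noisy spectra sampled from those
models (peak dropout, m/z jitter, spurious peaks). The noiseless
configuration reproduces the predicted spectra exactly, so ground truth
is always available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import POSITIVE, MoleculeStructure, parse_structure, precursor_mz, PROTONATION
from .features import FEATURE_NAMES, N_FEATURES
from .model import DEFAULT_CHAIN_DEPTH, TransitionModel
from .predict import predict
from .spectra import ENERGY_LEVELS, Peak, Spectrum

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1, "I": 1}


@dataclass
class FixtureConfig:
    """Knobs of the synthetic-data generator.

    Defaults emulate a clean Q-TOF acquisition of small metabolite-like
    molecules: occasional missing peaks, sub-tolerance mass jitter, and a
    rare spurious peak.
    """

    n_molecules: int = 30
    heavy_atom_range: tuple[int, int] = (3, 8)
    elements: tuple[str, ...] = ("C", "C", "C", "N", "O")  # draw weights by repetition
    ring_probability: float = 0.3
    dropout_prob: float = 0.05
    mz_jitter_sd: float = 0.002  # Da
    spurious_rate: float = 0.1  # probability of one extra noise peak
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ring_probability", "dropout_prob", "spurious_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be >= 0")
        unknown = set(self.elements) - set(_VALENCE)
        if unknown:
            raise ValueError(f"unsupported elements: {sorted(unknown)}")


def _random_molecule(rng: np.random.Generator, cfg: FixtureConfig) -> str | None:
    lo, hi = cfg.heavy_atom_range
    n = int(rng.integers(lo, hi + 1))
    symbols = [str(rng.choice(cfg.elements)) for _ in range(n)]
    # grow a random tree respecting valences
    rw = Chem.RWMol()
    for s in symbols:
        rw.AddAtom(Chem.Atom(s))
    degree = [0] * n
    for i in range(1, n):
        slots = [j for j in range(i) if degree[j] < _VALENCE[symbols[j]]]
        if not slots:
            return None
        j = int(rng.choice(slots))
        rw.AddBond(i, j, Chem.BondType.SINGLE)
        degree[i] += 1
        degree[j] += 1
    if n >= 3 and rng.random() < cfg.ring_probability:
        open_atoms = [i for i in range(n) if degree[i] < _VALENCE[symbols[i]]]
        rng.shuffle(open_atoms)
        for a in open_atoms:
            partners = [b for b in open_atoms
                        if b != a and rw.GetBondBetweenAtoms(a, b) is None]
            if partners:
                rw.AddBond(a, int(partners[0]), Chem.BondType.SINGLE)
                break
    mol = rw.GetMol()
    if Chem.SanitizeMol(mol, catchErrors=True) != Chem.SanitizeFlags.SANITIZE_NONE:
        return None
    return Chem.MolToSmiles(mol)


def generate_library(cfg: FixtureConfig) -> list[MoleculeStructure]:
    """A deduplicated, reproducible library of ``cfg.n_molecules``
    valence-legal connected structures."""
    rng = np.random.default_rng(cfg.seed)
    out: list[MoleculeStructure] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * max(cfg.n_molecules, 1)
    while len(out) < cfg.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not generate {cfg.n_molecules} unique molecules in "
                f"{max_attempts} attempts; constraints too tight")
        smiles = _random_molecule(rng, cfg)
        if smiles is None:
            continue
        mol = parse_structure(smiles)
        if mol.canonical_key in seen:
            continue
        seen.add(mol.canonical_key)
        out.append(mol)
    return out


#: Reference parameter values used as ground truth. Feature weights are
#: shared across energies (water/ammonia losses favored, heavier losses
#: disfavored); the self-transition bias drops with collision energy, so
#: the precursor survives low energy and shatters at high energy.
_REFERENCE_FEATURE_WEIGHTS = {
    "bond_order": 0.3,
    "aromatic_bond": -0.5,
    "ring_cleavage": -0.3,
    "h_offset": 0.1,
    "loss_H2O": 1.2,
    "loss_CO": 0.6,
    "loss_CO2": 0.5,
    "loss_NH3": 0.9,
    "loss_CH4": 0.2,
    "loss_CH2": 0.1,
    "loss_HCOOH": 0.4,
    "loss_other": 0.0,
    "loss_mass_scaled": -0.5,
    "child_heteroatoms": 0.2,
}
_REFERENCE_BIAS = {"low": 3.0, "medium": 1.0, "high": -1.0}


def reference_models(depth: int = DEFAULT_CHAIN_DEPTH) -> dict[str, TransitionModel]:
    """The fixed "true" single-energy models the generator samples from."""
    base = np.array([_REFERENCE_FEATURE_WEIGHTS[n] for n in FEATURE_NAMES])
    assert len(base) == N_FEATURES
    return {
        energy: TransitionModel(np.append(base, _REFERENCE_BIAS[energy]),
                                depth, energy)
        for energy in ENERGY_LEVELS
    }


def sample_spectra(mol: MoleculeStructure,
                   models: dict[str, TransitionModel],
                   cfg: FixtureConfig,
                   mode: str = POSITIVE,
                   rng: np.random.Generator | None = None,
                   clean: dict[str, Spectrum] | None = None) -> dict[str, Spectrum]:
    """Noisy observed spectra for one molecule under the given models.

    Starts from the deterministic predicted spectra and applies, per
    peak: dropout (never the precursor peak, so every sampled spectrum
    stays annotatable), Gaussian m/z jitter, and with probability
    ``spurious_rate`` one uniform spurious peak below the precursor.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if clean is None:
        clean = predict(mol, mode, models)
    prec_mz = precursor_mz(mol, PROTONATION[mode])
    out: dict[str, Spectrum] = {}
    for energy in ENERGY_LEVELS:
        peaks = []
        for p in clean[energy].peaks:
            is_precursor = abs(p.mz - prec_mz) <= 1e-5
            if not is_precursor and rng.random() < cfg.dropout_prob:
                continue
            mz = p.mz + (rng.normal(0.0, cfg.mz_jitter_sd)
                         if cfg.mz_jitter_sd > 0 else 0.0)
            peaks.append(Peak(mz, p.intensity))
        if cfg.spurious_rate > 0 and rng.random() < cfg.spurious_rate:
            lo = 15.0
            hi = max(prec_mz - 1.0, lo + 1.0)
            peaks.append(Peak(float(rng.uniform(lo, hi)),
                              float(rng.uniform(1.0, 30.0))))
        out[energy] = Spectrum(energy, peaks).base_normalized()
    return out


def generate_dataset(cfg: FixtureConfig,
                     models: dict[str, TransitionModel] | None = None,
                     mode: str = POSITIVE,
                     ) -> tuple[list[MoleculeStructure],
                                dict[str, TransitionModel],
                                list[dict[str, Spectrum]]]:
    """Library + reference models + one noisy spectrum set per molecule,
    all driven by ``cfg.seed``."""
    models = models or reference_models()
    library = generate_library(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    spectra = [sample_spectra(mol, models, cfg, mode=mode, rng=rng)
               for mol in library]
    return library, models, spectra
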