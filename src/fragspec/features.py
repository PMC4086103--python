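"""Cleavage feature map: a fixed-length numeric description of one
fragmentation event, scored linearly by the transition model.

The features are a compact, chemically motivated set: what kind of bond
broke, whether a ring opened, the net hydrogen rearrangement, which common
small neutral was lost, how heavy the loss was, and how heteroatom-rich
the charge-retaining side is.
"""

from __future__ import annotations

import numpy as np

from .fraggraph import FragmentationGraph, Transition

#: Common small neutral losses with dedicated indicator features.
#: CH3-type methyl loss appears as CH2/CH4 under the even-electron rule,
#: so the indicator covers the one-carbon, hydrogen-only losses.
COMMON_LOSSES: list[tuple[str, dict[str, int]]] = [
    ("loss_H2O", {"H": 2, "O": 1}),
    ("loss_CO", {"C": 1, "O": 1}),
    ("loss_CO2", {"C": 1, "O": 2}),
    ("loss_NH3", {"N": 1, "H": 3}),
    ("loss_CH4", {"C": 1, "H": 4}),
    ("loss_CH2", {"C": 1, "H": 2}),
    ("loss_HCOOH", {"C": 1, "H": 2, "O": 2}),
]

FEATURE_NAMES: list[str] = [
    "bond_order",
    "aromatic_bond",
    "ring_cleavage",
    "h_offset",
    *[name for name, _ in COMMON_LOSSES],
    "loss_other",
    "loss_mass_scaled",
    "child_heteroatoms",
]

N_FEATURES = len(FEATURE_NAMES)


def transition_features(graph: FragmentationGraph, tr: Transition) -> np.ndarray:
    """Feature vector Phi(parent, child) for one transition."""
    phi = np.zeros(N_FEATURES)
    phi[0] = tr.broken_bond_order
    phi[1] = 1.0 if tr.aromatic else 0.0
    phi[2] = 1.0 if tr.ring_cleavage else 0.0
    phi[3] = tr.h_offset
    loss = tr.neutral_loss_formula
    matched = False
    for k, (_name, formula) in enumerate(COMMON_LOSSES):
        if loss == formula:
            phi[4 + k] = 1.0
            matched = True
            break
    if not matched:
        phi[4 + len(COMMON_LOSSES)] = 1.0
    phi[5 + len(COMMON_LOSSES)] = tr.neutral_loss_mass / 100.0
    child = graph.node(tr.child_id).fragment
    phi[6 + len(COMMON_LOSSES)] = sum(1 for a in child.atoms if a != "C")
    return phi


def feature_matrix(graph: FragmentationGraph) -> np.ndarray:
    """Feature vectors for every transition, in transition-list order."""
    if not graph.transitions:
        return np.zeros((0, N_FEATURES))
    return np.vstack([transition_features(graph, t) for t in graph.transitions])
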