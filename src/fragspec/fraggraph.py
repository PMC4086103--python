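"""Systematic fragment enumeration: build the fragmentation graph of a
precursor ion by recursive bond disconnection.

Every single acyclic heavy-atom bond is broken once; ring systems are
opened by jointly cleaving each pair of bonds within the same smallest
ring. Either side of a disconnection may retain the charge, and each
charge-retaining side is emitted at net hydrogen offsets {-1, 0, +1}
relative to homolytic cleavage. Only even-electron species survive: a
fragment is kept iff its free-valence deficit (slots minus hydrogens) is
even, with per-atom valences frozen from the precursor. Under this rule a
single-bond homolysis survives only at offsets +/-1 and a two-bond ring
opening only at offset 0.

Fragment identity is the pair (canonical heavy-atom skeleton, total
hydrogen count): hydrogen placement after a rearrangement is ambiguous,
so fragments differing only in where the migrated hydrogen sits are the
same node. Ion m/z = fragment neutral-form mass +/- proton mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .chem import (
    ELEMENT_MASSES,
    NEGATIVE,
    POSITIVE,
    PROTON_MASS,
    ChemError,
    MoleculeStructure,
    formula_mass,
)

DEFAULT_MAX_DEPTH = 2
DEFAULT_NODE_CAP = 10_000


class GraphError(RuntimeError):
    """Raised when enumeration exceeds the configured node cap."""


@dataclass(frozen=True)
class Fragment:
    """A heavy-atom skeleton plus an explicit hydrogen budget.

    ``atoms`` are element symbols; ``bonds`` are (i, j, order, aromatic)
    with i < j; ``h`` is the per-atom hydrogen count (one deterministic
    realization — identity ignores placement); ``valence`` is the per-atom
    effective valence inherited from the precursor.
    """

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, int, bool], ...]
    h: tuple[int, ...]
    valence: tuple[int, ...]
    skeleton_key: str

    @property
    def total_h(self) -> int:
        return sum(self.h)

    @property
    def key(self) -> str:
        return f"{self.skeleton_key}|H{self.total_h}"

    @property
    def formula(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sym in self.atoms:
            counts[sym] = counts.get(sym, 0) + 1
        if self.total_h:
            counts["H"] = counts.get("H", 0) + self.total_h
        return counts

    def neutral_mass(self) -> float:
        return formula_mass(self.formula)


@dataclass
class FragmentNode:
    id: int
    fragment: Fragment
    ion_mass: float
    depth: int

    @property
    def smiles(self) -> str:
        return self.fragment.skeleton_key


@dataclass
class Transition:
    parent_id: int
    child_id: int
    neutral_loss_formula: dict[str, int]
    neutral_loss_mass: float
    # cleavage descriptors consumed by the feature map
    broken_bond_order: int = 1
    aromatic: bool = False
    ring_cleavage: bool = False
    h_offset: int = 0


@dataclass
class FragmentationGraph:
    nodes: list[FragmentNode]
    transitions: list[Transition]
    max_depth: int
    mode: str = POSITIVE

    def node(self, node_id: int) -> FragmentNode:
        return self.nodes[self._index[node_id]]

    @property
    def _index(self) -> dict[int, int]:
        return {n.id: i for i, n in enumerate(self.nodes)}

    def children_of(self, node_id: int) -> list[Transition]:
        return [t for t in self.transitions if t.parent_id == node_id]

    def parents_of(self, node_id: int) -> list[Transition]:
        return [t for t in self.transitions if t.child_id == node_id]


def _skeleton_mol(atoms: tuple[str, ...], bonds) -> Chem.Mol:
    rw = Chem.RWMol()
    for sym in atoms:
        rw.AddAtom(Chem.Atom(sym))
    for i, j, order, _arom in bonds:
        rw.AddBond(i, j, Chem.BondType.values[order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, catchErrors=True)
    return mol


def _make_fragment(atoms, bonds, h, valence) -> Fragment:
    key = Chem.MolToSmiles(_skeleton_mol(atoms, bonds))
    return Fragment(tuple(atoms), tuple(bonds), tuple(h), tuple(valence), key)


def precursor_fragment(mol: MoleculeStructure) -> Fragment:
    """Extract the heavy-atom skeleton and hydrogen budget of a parsed
    neutral molecule."""
    heavy = [a for a in mol.mol.GetAtoms() if a.GetSymbol() != "H"]
    if not heavy:
        # bare hydrogens (e.g. H2) have no skeleton; unsupported as precursor
        raise ChemError("precursor must contain at least one heavy atom")
    if len(Chem.GetMolFrags(mol.mol)) > 1:
        raise ChemError("precursor heavy-atom graph must be connected "
                        f"(got a multi-component structure: {mol.source!r})")
    index = {a.GetIdx(): i for i, a in enumerate(heavy)}
    atoms = tuple(a.GetSymbol() for a in heavy)
    h = [0] * len(heavy)
    bonds = []
    for a in heavy:
        h[index[a.GetIdx()]] = sum(1 for nb in a.GetNeighbors() if nb.GetSymbol() == "H")
    for b in mol.mol.GetBonds():
        i, j = b.GetBeginAtom(), b.GetEndAtom()
        if i.GetSymbol() == "H" or j.GetSymbol() == "H":
            continue
        bi, bj = sorted((index[i.GetIdx()], index[j.GetIdx()]))
        bonds.append((bi, bj, int(round(b.GetBondTypeAsDouble())), b.GetIsAromatic()))
    bonds.sort()
    valence = [0] * len(heavy)
    for i, j, order, _ in bonds:
        valence[i] += order
        valence[j] += order
    for i in range(len(heavy)):
        valence[i] += h[i]
    return _make_fragment(atoms, bonds, h, valence)


def ion_mass_of(fragment: Fragment, mode: str) -> float:
    delta = PROTON_MASS if mode == POSITIVE else -PROTON_MASS
    return fragment.neutral_mass() + delta


def _components(n_atoms: int, bonds) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j, _o, _a in bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen = [False] * n_atoms
    comps = []
    for start in range(n_atoms):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _ring_bond_sets(fragment: Fragment) -> list[list[int]]:
    """Indices (into fragment.bonds) of the bonds of each smallest ring."""
    mol = _skeleton_mol(fragment.atoms, fragment.bonds)
    Chem.FastFindRings(mol)
    bond_index = {}
    for pos, (i, j, _o, _a) in enumerate(fragment.bonds):
        bond_index[(i, j)] = pos
        bond_index[(j, i)] = pos
    rings = []
    for ring_bonds in mol.GetRingInfo().BondRings():
        positions = []
        for bidx in ring_bonds:
            b = mol.GetBondWithIdx(bidx)
            positions.append(bond_index[(b.GetBeginAtomIdx(), b.GetEndAtomIdx())])
        rings.append(sorted(positions))
    return rings


def _cleavages(fragment: Fragment) -> list[tuple[list[int], bool]]:
    """All cleavage events: ([bond positions], is_ring_cleavage)."""
    ring_positions: set[int] = set()
    rings = _ring_bond_sets(fragment)
    for ring in rings:
        ring_positions.update(ring)
    events: list[tuple[list[int], bool]] = []
    for pos in range(len(fragment.bonds)):
        if pos not in ring_positions:
            events.append(([pos], False))
    seen_pairs = set()
    for ring in rings:
        for a in range(len(ring)):
            for b in range(a + 1, len(ring)):
                pair = (ring[a], ring[b])
                if pair not in seen_pairs:
                    seen_pairs.add(pair)
                    events.append(([ring[a], ring[b]], True))
    return events


def _side_fragment(fragment: Fragment, comp: list[int], cut_atoms: set[int],
                   h_offset: int) -> Fragment | None:
    """Build one charge-retaining side at a net H offset; None if the
    offset is infeasible or yields an odd-electron species."""
    remap = {old: new for new, old in enumerate(comp)}
    atoms = tuple(fragment.atoms[i] for i in comp)
    bonds = tuple(
        (remap[i], remap[j], o, ar)
        for (i, j, o, ar) in fragment.bonds
        if i in remap and j in remap
    )
    valence = tuple(fragment.valence[i] for i in comp)
    h = [fragment.h[i] for i in comp]
    bondsum = [0] * len(atoms)
    for i, j, o, _ in bonds:
        bondsum[i] += o
        bondsum[j] += o
    slots = [valence[i] - bondsum[i] for i in range(len(atoms))]
    # deterministic H placement, cleavage sites first
    site_order = sorted(range(len(atoms)),
                        key=lambda i: (comp[i] not in cut_atoms, comp[i]))
    if h_offset == +1:
        for i in site_order:
            if h[i] < slots[i]:
                h[i] += 1
                break
        else:
            return None
    elif h_offset == -1:
        for i in site_order:
            if h[i] > 0:
                h[i] -= 1
                break
        else:
            return None
    deficit = sum(slots) - sum(h)
    if deficit < 0 or deficit % 2 != 0:
        return None
    return _make_fragment(atoms, bonds, h, valence)


def enumerate_children(parent: Fragment, mode: str) -> list[tuple[Fragment, Transition]]:
    """All distinct child fragments reachable from ``parent`` by one
    cleavage event, with their transition descriptors.

    Transition ids are left unset (-1); the graph builder fills them in.
    Duplicates by (skeleton, H count) are merged, keeping the first
    deterministic occurrence.
    """
    results: list[tuple[Fragment, Transition]] = []
    seen: set[str] = set()
    parent_mass = ion_mass_of(parent, mode)
    for positions, is_ring in _cleavages(parent):
        kept = [b for p, b in enumerate(parent.bonds) if p not in positions]
        comps = _components(len(parent.atoms), kept)
        if len(comps) != 2:
            continue
        broken = [parent.bonds[p] for p in positions]
        cut_atoms = {i for (i, j, _o, _a) in broken for i in (i, j)}
        order_sum = sum(o for (_i, _j, o, _a) in broken)
        any_aromatic = any(a for (_i, _j, _o, a) in broken)
        for comp in comps:
            for h_offset in (-1, 0, +1):
                child = _side_fragment(parent, comp, cut_atoms, h_offset)
                if child is None:
                    continue
                loss_h = parent.total_h - child.total_h
                if loss_h < 0:
                    continue
                if child.key in seen:
                    continue
                loss: dict[str, int] = {}
                in_comp = set(comp)
                for i, sym in enumerate(parent.atoms):
                    if i not in in_comp:
                        loss[sym] = loss.get(sym, 0) + 1
                if loss_h:
                    loss["H"] = loss.get("H", 0) + loss_h
                loss_mass = formula_mass(loss)
                if loss_mass <= 0:
                    continue
                seen.add(child.key)
                results.append((
                    child,
                    Transition(
                        parent_id=-1,
                        child_id=-1,
                        neutral_loss_formula=loss,
                        neutral_loss_mass=loss_mass,
                        broken_bond_order=order_sum,
                        aromatic=any_aromatic,
                        ring_cleavage=is_ring,
                        h_offset=h_offset,
                    ),
                ))
    # sanity: every child strictly lighter than the parent
    assert all(ion_mass_of(c, mode) < parent_mass for c, _ in results)
    return results


def build_graph(precursor: MoleculeStructure, mode: str,
                max_depth: int = DEFAULT_MAX_DEPTH,
                node_cap: int = DEFAULT_NODE_CAP) -> FragmentationGraph:
    """Breadth-first enumeration of the fragmentation graph to ``max_depth``.

    Node numbering is deterministic: level by level, new nodes sorted by
    ascending ion mass then canonical key. Raises :class:`GraphError` if
    the node cap is exceeded.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if mode not in (POSITIVE, NEGATIVE):
        raise ChemError(f"unknown ionization mode {mode!r}")
    root = precursor_fragment(precursor)
    nodes = [FragmentNode(0, root, ion_mass_of(root, mode), 0)]
    by_key = {root.key: 0}
    transitions: list[Transition] = []
    edge_seen: set[tuple[int, int]] = set()
    frontier = [0]
    for depth in range(1, max_depth + 1):
        level: dict[str, tuple[Fragment, float]] = {}
        level_edges: list[tuple[int, str, Transition]] = []
        for pid in frontier:
            parent = nodes[pid]
            if len(parent.fragment.atoms) < 2:
                continue
            for child, tr in enumerate_children(parent.fragment, mode):
                if child.key not in by_key and child.key not in level:
                    level[child.key] = (child, ion_mass_of(child, mode))
                level_edges.append((pid, child.key, tr))
        new_ids = []
        for key, (frag, mass) in sorted(level.items(), key=lambda kv: (kv[1][1], kv[0])):
            nid = len(nodes)
            if nid >= node_cap:
                raise GraphError(f"fragmentation graph node cap exceeded ({node_cap})")
            nodes.append(FragmentNode(nid, frag, mass, depth))
            by_key[key] = nid
            new_ids.append(nid)
        for pid, key, tr in level_edges:
            cid = by_key[key]
            if (pid, cid) in edge_seen:
                continue
            edge_seen.add((pid, cid))
            tr.parent_id, tr.child_id = pid, cid
            transitions.append(tr)
        if not new_ids:
            break
        frontier = new_ids
    transitions.sort(key=lambda t: (t.parent_id, t.child_id))
    return FragmentationGraph(nodes=nodes, transitions=transitions,
                              max_depth=max_depth, mode=mode)


def prune_graph(graph: FragmentationGraph, keep_ids: set[int]) -> FragmentationGraph:
    """Induced subgraph over ``keep_ids`` plus every node on a root path
    to a kept node (the precursor is always kept)."""
    ids = set(graph._index)
    unknown = set(keep_ids) - ids
    if unknown:
        raise KeyError(f"keep_ids not in graph: {sorted(unknown)}")
    parents: dict[int, list[int]] = {}
    for t in graph.transitions:
        parents.setdefault(t.child_id, []).append(t.parent_id)
    keep = set(keep_ids) | {0}
    stack = list(keep)
    while stack:
        nid = stack.pop()
        for pid in parents.get(nid, []):
            if pid not in keep:
                keep.add(pid)
                stack.append(pid)
    nodes = [n for n in graph.nodes if n.id in keep]
    transitions = [t for t in graph.transitions
                   if t.parent_id in keep and t.child_id in keep]
    transitions.sort(key=lambda t: (t.parent_id, t.child_id))
    return FragmentationGraph(nodes=nodes, transitions=transitions,
                              max_depth=graph.max_depth, mode=graph.mode)
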