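"""Local graph-invariant attributes of the hydrogen-suppressed molecular graph.

Complements the SMILES-string attributes with elementary topological
descriptors computed per atom:

* ``EC0`` — Morgan extended connectivity of order zero (the heavy-atom degree);
* ``VS2``/``VS3`` — valence shells: number of atoms at shortest-path distance
  exactly 2 / exactly 3;
* ``PT2``/``PT3`` — number of simple paths of length 2 / 3 edges starting at
  the atom (no repeated vertices);
* ``NNC`` — nearest-neighbour composition, the pair (carbon neighbours,
  non-carbon neighbours).

Each per-atom value becomes a 12-character key ``KIND-Ev.....`` where ``E`` is
the element symbol (lowercase when aromatic, so aromatic and aliphatic
environments stay distinct) and ``v`` the integer value.  The key string
format is a package convention; it only needs to be canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .records import KEY_WIDTH, AttributeKey, AttributeProfile
from .smiles_attributes import SmilesError

KINDS = ("EC0", "VS2", "VS3", "PT2", "PT3", "NNC")


@dataclass
class MolGraph:
    """Hydrogen-suppressed molecular graph.

    ``atoms`` holds (element symbol, aromatic flag) per atom; ``adjacency``
    is a symmetric list of neighbour index lists.
    """

    atoms: list[tuple[str, bool]] = field(default_factory=list)
    adjacency: list[list[int]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.adjacency) // 2

    def symbol(self, i: int) -> str:
        sym, aromatic = self.atoms[i]
        return sym.lower() if aromatic else sym


@dataclass(frozen=True)
class VertexInvariant:
    atom: int
    kind: str
    value: int


def build_graph(smiles: str) -> MolGraph:
    """Parse SMILES into a hydrogen-suppressed graph, canonical atom order."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"cannot parse SMILES: {smiles!r}")
    g = MolGraph()
    g.atoms = [(a.GetSymbol(), a.GetIsAromatic()) for a in mol.GetAtoms()]
    g.adjacency = [
        [nb.GetIdx() for nb in a.GetNeighbors()] for a in mol.GetAtoms()
    ]
    return g


def _shell_sizes(g: MolGraph, start: int) -> tuple[int, int]:
    """(atoms at distance exactly 2, atoms at distance exactly 3) by BFS."""
    dist = {start: 0}
    frontier = [start]
    d = 0
    while frontier and d < 3:
        d += 1
        nxt = []
        for v in frontier:
            for w in g.adjacency[v]:
                if w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt
    counts = [0, 0, 0, 0]
    for d in dist.values():
        counts[d] += 1
    return counts[2], counts[3]


def _path_counts(g: MolGraph, start: int) -> tuple[int, int]:
    """(simple paths of 2 edges, of 3 edges) starting at ``start``."""
    p2 = p3 = 0
    for a in g.adjacency[start]:
        for b in g.adjacency[a]:
            if b == start:
                continue
            p2 += 1
            for c in g.adjacency[b]:
                if c != start and c != a:
                    p3 += 1
    return p2, p3


def vertex_invariants(g: MolGraph) -> list[VertexInvariant]:
    """All six invariant kinds for every atom."""
    out: list[VertexInvariant] = []
    for v in range(g.n_atoms):
        ec0 = len(g.adjacency[v])
        vs2, vs3 = _shell_sizes(g, v)
        pt2, pt3 = _path_counts(g, v)
        carbon = sum(1 for w in g.adjacency[v] if g.atoms[w][0] == "C")
        non_carbon = ec0 - carbon
        nnc = 10 * carbon + non_carbon
        for kind, value in (
            ("EC0", ec0), ("VS2", vs2), ("VS3", vs3),
            ("PT2", pt2), ("PT3", pt3), ("NNC", nnc),
        ):
            out.append(VertexInvariant(v, kind, value))
    return out


def graph_attribute_keys(
    g: MolGraph, invariants: list[VertexInvariant] | None = None
) -> list[AttributeKey]:
    """Render per-atom invariants as canonical 12-character keys."""
    if invariants is None:
        invariants = vertex_invariants(g)
    keys = []
    for inv in invariants:
        text = f"{inv.kind}-{g.symbol(inv.atom)}{inv.value}"
        keys.append(AttributeKey(text.ljust(KEY_WIDTH, "."), inv.kind))
    return keys


def graph_attribute_profile(molecule_id: str, smiles: str) -> AttributeProfile:
    """AttributeProfile of the graph-invariant attributes of one molecule."""
    g = build_graph(smiles)
    profile = AttributeProfile(molecule_id)
    for key in graph_attribute_keys(g):
        profile.add(key)
    return profile


def full_attribute_profile(molecule_id: str, smiles: str) -> AttributeProfile:
    """SMILES attributes plus graph invariants in one profile."""
    from .smiles_attributes import smiles_attribute_profile

    return smiles_attribute_profile(molecule_id, smiles).merge(
        graph_attribute_profile(molecule_id, smiles)
    )
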