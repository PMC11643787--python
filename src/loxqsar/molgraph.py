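"""Molecular graphs for 2D descriptor calculation.

The pipeline works on plain undirected molecular graphs: atoms carry an
element symbol, a formal charge and a ring flag; bonds carry an order
(1, 2, 3 or aromatic).  Stereochemistry and 3D coordinates are ignored —
every descriptor downstream is a pure graph descriptor.

Parsing of SMILES and SDF goes through RDKit; everything after parsing
(ring perception, hydrogen addition, the V2000 writer) operates on
:class:`MolecularGraph` directly so that synthetic graphs built without
RDKit go through exactly the same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "StructureParseError",
    "read_structures",
    "add_explicit_hydrogens",
    "perceive_rings",
    "write_sdf",
]

logger = logging.getLogger(__name__)

AROMATIC = "ar"

#: Default valences used for implicit-hydrogen completion.  The effective
#: valence of an atom is ``DEFAULT_VALENCE[element] + formal_charge``, which
#: gives the common organic cases (N+ -> 4, O- -> 1) correctly.
DEFAULT_VALENCE = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "Si": 4, "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
}


class StructureParseError(ValueError):
    """Raised when an input record cannot be parsed into a molecular graph."""


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int = 0
    in_ring: bool = False
    #: Hydrogen count hint.  ``None`` means "derive from the valence table";
    #: parsers that know better (RDKit's aromatic perception) set it.
    n_h: int | None = None


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float | str = 1  # 1, 2, 3 or AROMATIC


@dataclass
class MolecularGraph:
    """Undirected molecular graph; no self-loops, at most one bond per pair."""

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"invalid bond endpoints ({b.i}, {b.j}) for {n} atoms")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond between atoms {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj

    def bond_order_sum(self, idx: int) -> float:
        """Sum of bond orders at an atom; aromatic bonds count 1.5."""
        total = 0.0
        for b in self.bonds:
            if idx in (b.i, b.j):
                total += 1.5 if b.order == AROMATIC else float(b.order)
        return total

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]


def _bond_order_from_rdkit(bond) -> float | str:
    from rdkit import Chem

    if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
        return AROMATIC
    return {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
    }.get(bond.GetBondType(), 1)


def _graph_from_rdkit(mol, name: str = "") -> MolecularGraph:
    atoms = [
        Atom(
            element=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            in_ring=a.IsInRing(),
            n_h=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _bond_order_from_rdkit(b))
        for b in mol.GetBonds()
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, name=name)


def largest_fragment(graph: MolecularGraph) -> MolecularGraph:
    """Keep only the largest connected component (salt stripping).

    Ties are broken by the component containing the lowest atom index, so
    the reduction is deterministic.
    """
    g = graph.to_networkx()
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    if len(comps) <= 1:
        return graph
    logger.warning("multi-fragment structure %r: keeping largest of %d fragments",
                   graph.name, len(comps))
    keep = sorted(comps[0])
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [graph.atoms[i] for i in keep]
    bonds = [Bond(remap[b.i], remap[b.j], b.order)
             for b in graph.bonds if b.i in remap and b.j in remap]
    return MolecularGraph(atoms=atoms, bonds=bonds, name=graph.name, meta=dict(graph.meta))


def read_structures(source: str | Path, fmt: str = "smiles") -> list[MolecularGraph]:
    """Read molecules from SMILES text/file or an SDF (V2000) file.

    SMILES input is one record per line, optionally ``smiles<TAB>id``.
    ``source`` may be a path or raw text.  Records appear in input order;
    a malformed record raises :class:`StructureParseError` naming its
    (1-based) index.  Multi-fragment records are reduced to their largest
    connected component.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    fmt = fmt.lower()
    if fmt not in {"smiles", "sdf"}:
        raise ValueError(f"unsupported format {fmt!r}")

    text: str
    path = Path(str(source))
    try:
        is_file = path.is_file()
    except OSError:
        is_file = False
    if is_file:
        text = path.read_text(encoding="utf-8")
    else:
        text = str(source)
    if not text.strip():
        raise StructureParseError("empty input")

    graphs: list[MolecularGraph] = []
    if fmt == "smiles":
        records = [ln for ln in text.splitlines() if ln.strip()]
        for idx, line in enumerate(records, start=1):
            parts = line.split("\t")
            smi = parts[0].strip()
            name = parts[1].strip() if len(parts) > 1 else f"mol{idx}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise StructureParseError(f"record {idx}: cannot parse SMILES {smi!r}")
            _check_elements(mol, idx)
            graphs.append(largest_fragment(_graph_from_rdkit(mol, name=name)))
    else:
        blocks = _split_sdf(text)
        for idx, block in enumerate(blocks, start=1):
            mol = Chem.MolFromMolBlock(block, sanitize=True)
            if mol is None:
                raise StructureParseError(f"record {idx}: cannot parse SDF block")
            _check_elements(mol, idx)
            name = block.splitlines()[0].strip() or f"mol{idx}"
            graphs.append(largest_fragment(_graph_from_rdkit(mol, name=name)))
    return graphs


def _check_elements(mol, idx: int) -> None:
    for a in mol.GetAtoms():
        if a.GetSymbol() == "*" or a.GetAtomicNum() == 0:
            raise StructureParseError(f"record {idx}: unsupported element {a.GetSymbol()!r}")


def _split_sdf(text: str) -> list[str]:
    blocks = [b.strip("\n") for b in text.split("$$$$")]
    return [b + "\n" for b in blocks if b.strip()]


def effective_valence(atom: Atom) -> int:
    try:
        base = DEFAULT_VALENCE[atom.element]
    except KeyError:
        raise ValueError(f"no valence entry for element {atom.element!r}") from None
    return base + atom.charge


def add_explicit_hydrogens(graph: MolecularGraph) -> MolecularGraph:
    """Return a copy with explicit hydrogen atoms appended.

    Hydrogen counts come from the per-atom ``n_h`` hint when present
    (set by the RDKit parser), otherwise from the valence table: the
    deficit between the effective valence and the rounded bond-order sum
    (aromatic bonds count 1.5).  Idempotent: atoms already saturated get
    no further hydrogens.
    """
    atoms = list(graph.atoms)
    bonds = list(graph.bonds)
    explicit_h: list[int] = [0] * graph.n_atoms
    for b in graph.bonds:
        if graph.atoms[b.i].element == "H":
            explicit_h[b.j] += 1
        if graph.atoms[b.j].element == "H":
            explicit_h[b.i] += 1

    for idx, atom in enumerate(graph.atoms):
        if atom.element == "H":
            continue
        if atom.n_h is not None:
            missing = atom.n_h - explicit_h[idx]
        else:
            deficit = effective_valence(atom) - round(graph.bond_order_sum(idx))
            missing = deficit
        for _ in range(max(0, missing)):
            atoms.append(Atom(element="H", n_h=0))
            bonds.append(Bond(idx, len(atoms) - 1, 1))
        # saturate the hint so a second application is a no-op
        atoms[idx] = replace(atom, n_h=max(atom.n_h if atom.n_h is not None else 0, explicit_h[idx] + max(0, missing)))
    return MolecularGraph(atoms=atoms, bonds=bonds, name=graph.name, meta=dict(graph.meta))


def perceive_rings(graph: MolecularGraph) -> MolecularGraph:
    """Return a copy with ``in_ring`` set exactly for atoms on cycles.

    An atom lies on a cycle iff it is incident to at least one non-bridge
    edge of the graph.
    """
    g = graph.to_networkx()
    bridges = set(frozenset(e) for e in nx.bridges(g))
    ring_atoms: set[int] = set()
    for b in graph.bonds:
        if frozenset((b.i, b.j)) not in bridges:
            ring_atoms.update((b.i, b.j))
    atoms = [replace(a, in_ring=(i in ring_atoms)) for i, a in enumerate(graph.atoms)]
    return MolecularGraph(atoms=atoms, bonds=graph.bonds, name=graph.name, meta=dict(graph.meta))


_SDF_ORDER = {1: 1, 2: 2, 3: 3, AROMATIC: 4}


def write_sdf(graphs: list[MolecularGraph] | MolecularGraph, path: str | Path | None = None) -> str:
    """Write graphs as an SDF (V2000, 2D-null coordinates) string or file."""
    if isinstance(graphs, MolecularGraph):
        graphs = [graphs]
    out: list[str] = []
    for g in graphs:
        lines = [g.name or "", "  loxqsar", ""]
        lines.append(f"{g.n_atoms:>3}{len(g.bonds):>3}  0  0  0  0  0  0  0  0999 V2000")
        for a in g.atoms:
            lines.append(f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {a.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
        for b in g.bonds:
            lines.append(f"{b.i + 1:>3}{b.j + 1:>3}{_SDF_ORDER[b.order]:>3}  0")
        charged = [(i + 1, a.charge) for i, a in enumerate(g.atoms) if a.charge]
        for k in range(0, len(charged), 8):
            chunk = charged[k:k + 8]
            lines.append("M  CHG" + f"{len(chunk):>3}" + "".join(f"{i:>4}{c:>4}" for i, c in chunk))
        lines.append("M  END")
        lines.append("$$$$")
        out.append("\n".join(lines))
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
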