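"""Substructural (MNA, QNA) and whole-molecule descriptors.

Two descriptor families drive every regression model in the pipeline:

* **MNA** (Multilevel Neighborhoods of Atoms): for every atom a canonical
  string is built recursively — the level-0 descriptor is the atom's mark
  (element symbol, prefixed with ``-`` when the atom is acyclic), and the
  level-k descriptor is ``mark(D1D2...)`` where the ``Di`` are the
  neighbors' level-(k-1) descriptors in lexicographic order.  A molecule is
  the multiset of these strings over all atoms and levels; explicit
  hydrogens are included.

* **QNA** (Quantitative Neighborhoods of Atoms): every heavy atom gets a
  real pair (P, Q) coupling atomic ionization potential IP and electron
  affinity EA through the connectivity.  With B_k = IP_k - EA_k,
  A_k = (IP_k + EA_k)/2, C the heavy-atom adjacency matrix and
  M = D_B^{-1/2} exp(-C/2) D_B^{-1/2}:  P_i = sum_k M_ik and
  Q_i = sum_k M_ik A_k.  The (P, Q) point cloud is turned into a
  fixed-length vector by atom-averaged Chebyshev products
  T_a(p)T_b(q) of the affinely scaled-and-clipped values.

Three whole-molecule descriptors (topological length, topological volume,
lipophilicity) accompany both families in every model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numpy.polynomial import chebyshev
from scipy.linalg import expm

from .elements import ElementProperties, load_default_properties
from .molgraph import MolecularGraph, add_explicit_hydrogens, perceive_rings

__all__ = [
    "MNADescriptor",
    "QNAPoint",
    "QNAScaling",
    "DescriptorVector",
    "DescriptorConfig",
    "Featurizer",
    "mna_atom_mark",
    "mna_descriptors",
    "build_vocabulary",
    "qna_values",
    "qna_features",
    "topological_length",
    "topological_volume",
    "lipophilicity",
]

WHOLE_MOLECULE_NAMES = ("top_length", "top_volume", "lipophilicity")


@dataclass(frozen=True)
class MNADescriptor:
    text: str
    level: int
    count: int


@dataclass(frozen=True)
class QNAPoint:
    atom: int
    p: float
    q: float


@dataclass(frozen=True)
class DescriptorVector:
    mna_counts: dict[str, int]
    qna_features: np.ndarray
    whole_molecule: tuple[int, float, float]  # (length, volume, lipophilicity)


def mna_atom_mark(graph: MolecularGraph, idx: int) -> str:
    """Atom mark: element symbol, ``-``-prefixed when the atom is acyclic."""
    atom = graph.atoms[idx]
    return atom.element if atom.in_ring else "-" + atom.element


def mna_descriptors(graph: MolecularGraph, max_level: int = 2) -> Counter[str]:
    """Multiset of MNA descriptor strings for all atoms, levels 0..max_level.

    The graph should have explicit hydrogens and perceived rings; use
    :class:`Featurizer` for end-to-end preparation.
    """
    if max_level < 0:
        raise ValueError("max_level must be >= 0")
    marks = [mna_atom_mark(graph, i) for i in range(graph.n_atoms)]
    adj = graph.neighbors()
    counts: Counter[str] = Counter()
    level_strings = list(marks)
    counts.update(level_strings)
    for _ in range(max_level):
        nxt = [
            marks[i] + "(" + "".join(sorted(level_strings[j] for j in adj[i])) + ")"
            for i in range(graph.n_atoms)
        ]
        counts.update(nxt)
        level_strings = nxt
    return counts


def mna_descriptor_list(graph: MolecularGraph, max_level: int = 2) -> list[MNADescriptor]:
    """Per-level MNA descriptors with multiplicities."""
    if max_level < 0:
        raise ValueError("max_level must be >= 0")
    marks = [mna_atom_mark(graph, i) for i in range(graph.n_atoms)]
    adj = graph.neighbors()
    out: list[MNADescriptor] = []
    level_strings = list(marks)
    for level in range(max_level + 1):
        if level > 0:
            level_strings = [
                marks[i] + "(" + "".join(sorted(level_strings[j] for j in adj[i])) + ")"
                for i in range(graph.n_atoms)
            ]
        for text, count in sorted(Counter(level_strings).items()):
            out.append(MNADescriptor(text=text, level=level, count=count))
    return out


def build_vocabulary(
    multisets: list[Counter[str]],
    min_count: int = 1,
    max_size: int | None = None,
) -> list[str]:
    """Sorted union of descriptor strings over training multisets.

    ``min_count`` keeps only descriptors present in at least that many
    molecules; ``max_size`` caps the vocabulary at the most frequent strings
    (ties broken lexicographically) — both reduce the descriptor space the
    way any practical substructure-count model must.
    """
    if not multisets:
        raise ValueError("at least one molecule required to build a vocabulary")
    presence: Counter[str] = Counter()
    for ms in multisets:
        presence.update(set(ms))
    kept = [s for s, c in presence.items() if c >= min_count]
    if max_size is not None and len(kept) > max_size:
        kept.sort(key=lambda s: (-presence[s], s))
        kept = kept[:max_size]
    return sorted(kept)


def _heavy_subgraph(graph: MolecularGraph) -> tuple[list[int], np.ndarray]:
    heavy = graph.heavy_indices()
    pos = {a: k for k, a in enumerate(heavy)}
    n = len(heavy)
    adj = np.zeros((n, n))
    for b in graph.bonds:
        if b.i in pos and b.j in pos:
            adj[pos[b.i], pos[b.j]] = adj[pos[b.j], pos[b.i]] = 1.0
    return heavy, adj


def qna_values(graph: MolecularGraph, props: ElementProperties | None = None) -> list[QNAPoint]:
    """Per-heavy-atom (P, Q) pairs from the matrix-exponential coupling."""
    if props is None:
        props = load_default_properties()
    heavy, adj = _heavy_subgraph(graph)
    if not heavy:
        raise ValueError("graph has no heavy atoms")
    ip = np.empty(len(heavy))
    ea = np.empty(len(heavy))
    for k, a in enumerate(heavy):
        sym = graph.atoms[a].element
        if sym not in props:
            raise KeyError(f"no property entry for element {sym!r}")
        e = props[sym]
        ip[k], ea[k] = e.ip_ev, e.ea_ev
    b = ip - ea
    a_mid = 0.5 * (ip + ea)
    d_inv_sqrt = 1.0 / np.sqrt(b)
    m = (d_inv_sqrt[:, None] * expm(-0.5 * adj)) * d_inv_sqrt[None, :]
    p = m.sum(axis=1)
    q = m @ a_mid
    return [QNAPoint(atom=heavy[k], p=float(p[k]), q=float(q[k])) for k in range(len(heavy))]


@dataclass(frozen=True)
class QNAScaling:
    """Affine map of training P/Q ranges onto [-1, 1], clipping outside."""

    p_min: float
    p_max: float
    q_min: float
    q_max: float

    @classmethod
    def fit(cls, point_sets: list[list[QNAPoint]]) -> "QNAScaling":
        ps = [pt.p for pts in point_sets for pt in pts]
        qs = [pt.q for pts in point_sets for pt in pts]
        if not ps:
            raise ValueError("no QNA points to fit scaling on")
        return cls(min(ps), max(ps), min(qs), max(qs))

    def _scale(self, x: np.ndarray, lo: float, hi: float) -> np.ndarray:
        if hi <= lo:
            # degenerate training range: every value maps to the center
            return np.zeros_like(x)
        return np.clip(2.0 * (x - lo) / (hi - lo) - 1.0, -1.0, 1.0)

    def apply(self, points: list[QNAPoint]) -> tuple[np.ndarray, np.ndarray]:
        p = np.array([pt.p for pt in points])
        q = np.array([pt.q for pt in points])
        return self._scale(p, self.p_min, self.p_max), self._scale(q, self.q_min, self.q_max)


def qna_features(points: list[QNAPoint], degree: int, scaling: QNAScaling | None = None) -> np.ndarray:
    """Atom-averaged Chebyshev products T_a(p)T_b(q), 0 <= a,b <= degree.

    Returned flat vector has length ``(degree+1)**2`` with index
    ``a*(degree+1)+b``.  Without an explicit training scaling the point
    cloud's own range is used.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if not points:
        raise ValueError("at least one QNA point required")
    if scaling is None:
        scaling = QNAScaling.fit([points])
    p_hat, q_hat = scaling.apply(points)
    vp = chebyshev.chebvander(p_hat, degree)  # (n_atoms, degree+1)
    vq = chebyshev.chebvander(q_hat, degree)
    return np.einsum("ia,ib->ab", vp, vq).ravel() / len(points)


def topological_length(graph: MolecularGraph) -> int:
    """Heavy-atom graph diameter in bonds."""
    heavy = graph.heavy_indices()
    if not heavy:
        raise ValueError("graph has no heavy atoms")
    g = graph.to_networkx().subgraph(heavy)
    if not nx.is_connected(g):
        raise ValueError("disconnected heavy-atom graph; reduce fragments first")
    if len(heavy) == 1:
        return 0
    return nx.diameter(g)


def topological_volume(graph: MolecularGraph, props: ElementProperties | None = None) -> float:
    """Additive covalent-sphere volume over heavy atoms (Å³)."""
    if props is None:
        props = load_default_properties()
    heavy = graph.heavy_indices()
    if not heavy:
        raise ValueError("graph has no heavy atoms")
    total = 0.0
    for i in heavy:
        sym = graph.atoms[i].element
        if sym not in props:
            raise KeyError(f"no covalent radius for element {sym!r}")
        total += (4.0 / 3.0) * np.pi * props[sym].r_cov_a ** 3
    return float(total)


def lipophilicity(graph: MolecularGraph, props: ElementProperties | None = None) -> float:
    """Atomic additive logP proxy over heavy atoms."""
    if props is None:
        props = load_default_properties()
    heavy = graph.heavy_indices()
    if not heavy:
        raise ValueError("graph has no heavy atoms")
    total = 0.0
    for i in heavy:
        sym = graph.atoms[i].element
        if sym not in props:
            raise KeyError(f"no lipophilicity contribution for element {sym!r}")
        total += props[sym].logp_contrib
    return float(total)


@dataclass(frozen=True)
class DescriptorConfig:
    mna_level: int = 2
    qna_degree: int = 3
    mna_min_count: int = 3
    mna_max_columns: int = 150


class Featurizer:
    """Fit descriptor spaces on a training set, transform any molecule set.

    Handles structure preparation (ring perception, explicit hydrogens for
    MNA), the MNA vocabulary, and the QNA scaling bounds; produces named
    descriptor matrices per family, each ending with the three
    whole-molecule columns.
    """

    def __init__(self, config: DescriptorConfig | None = None,
                 props: ElementProperties | None = None):
        self.config = config or DescriptorConfig()
        self.props = props or load_default_properties()
        self.vocabulary: list[str] | None = None
        self.qna_scaling: QNAScaling | None = None

    # -- preparation -------------------------------------------------
    def prepare(self, graph: MolecularGraph) -> MolecularGraph:
        return add_explicit_hydrogens(perceive_rings(graph))

    def mna_multiset(self, graph: MolecularGraph) -> Counter[str]:
        return mna_descriptors(self.prepare(graph), self.config.mna_level)

    # -- fitting -----------------------------------------------------
    def fit(self, graphs: list[MolecularGraph]) -> "Featurizer":
        if not graphs:
            raise ValueError("cannot fit a featurizer on an empty set")
        multisets = [self.mna_multiset(g) for g in graphs]
        self.vocabulary = build_vocabulary(
            multisets,
            min_count=self.config.mna_min_count,
            max_size=self.config.mna_max_columns,
        )
        self.qna_scaling = QNAScaling.fit([qna_values(g, self.props) for g in graphs])
        return self

    @property
    def qna_column_names(self) -> list[str]:
        d = self.config.qna_degree + 1
        return [f"qna_T{a}_{b}" for a in range(d) for b in range(d)]

    def family_columns(self, family: str) -> list[str]:
        if family == "QNA":
            return self.qna_column_names + list(WHOLE_MOLECULE_NAMES)
        if family == "MNA":
            assert self.vocabulary is not None, "featurizer not fitted"
            return self.vocabulary + list(WHOLE_MOLECULE_NAMES)
        raise ValueError(f"unknown descriptor family {family!r}")

    # -- transforming ------------------------------------------------
    def whole_molecule(self, graph: MolecularGraph) -> tuple[int, float, float]:
        return (
            topological_length(graph),
            topological_volume(graph, self.props),
            lipophilicity(graph, self.props),
        )

    def describe(self, graph: MolecularGraph) -> DescriptorVector:
        prepared = self.prepare(graph)
        return DescriptorVector(
            mna_counts=dict(mna_descriptors(prepared, self.config.mna_level)),
            qna_features=qna_features(
                qna_values(graph, self.props), self.config.qna_degree, self.qna_scaling
            ),
            whole_molecule=self.whole_molecule(graph),
        )

    def transform(self, graphs: list[MolecularGraph], family: str) -> pd.DataFrame:
        """Descriptor matrix (molecules x named columns) for one family."""
        cols = self.family_columns(family)
        rows = np.zeros((len(graphs), len(cols)))
        if family == "QNA":
            for r, g in enumerate(graphs):
                feats = qna_features(
                    qna_values(g, self.props), self.config.qna_degree, self.qna_scaling
                )
                rows[r, : feats.size] = feats
                rows[r, feats.size:] = self.whole_molecule(g)
        else:
            vocab_index = {s: k for k, s in enumerate(self.vocabulary or [])}
            nv = len(vocab_index)
            for r, g in enumerate(graphs):
                for s, c in self.mna_multiset(g).items():
                    k = vocab_index.get(s)
                    if k is not None:
                        rows[r, k] = c
                rows[r, nv:] = self.whole_molecule(g)
        return pd.DataFrame(rows, columns=cols)

    # -- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        assert self.vocabulary is not None and self.qna_scaling is not None
        return {
            "config": {
                "mna_level": self.config.mna_level,
                "qna_degree": self.config.qna_degree,
                "mna_min_count": self.config.mna_min_count,
                "mna_max_columns": self.config.mna_max_columns,
            },
            "vocabulary": self.vocabulary,
            "qna_scaling": [
                self.qna_scaling.p_min, self.qna_scaling.p_max,
                self.qna_scaling.q_min, self.qna_scaling.q_max,
            ],
        }

    @classmethod
    def from_dict(cls, data: dict, props: ElementProperties | None = None) -> "Featurizer":
        fz = cls(DescriptorConfig(**data["config"]), props=props)
        fz.vocabulary = list(data["vocabulary"])
        fz.qna_scaling = QNAScaling(*data["qna_scaling"])
        return fz
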