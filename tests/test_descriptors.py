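"""MNA recursion, QNA matrix-exponential values, whole-molecule descriptors."""

import numpy as np
import pytest

import loxqsar as lq
from loxqsar.descriptors import (
    Featurizer,
    QNAScaling,
    build_vocabulary,
    lipophilicity,
    mna_atom_mark,
    mna_descriptors,
    qna_features,
    qna_values,
    topological_length,
    topological_volume,
)
from loxqsar.molgraph import Atom, Bond, MolecularGraph, add_explicit_hydrogens, perceive_rings

from conftest import permute_graph


def prepared(g):
    return add_explicit_hydrogens(perceive_rings(g))


class TestMnaMarks:
    def test_cyclic_atom_unprefixed(self, benzene):
        g = perceive_rings(benzene)
        assert mna_atom_mark(g, 0) == "C"

    def test_acyclic_atom_prefixed(self, ethanol):
        g = perceive_rings(ethanol)
        oxygens = [i for i, a in enumerate(g.atoms) if a.element == "O"]
        assert mna_atom_mark(g, oxygens[0]) == "-O"

    def test_symmetry_equivalent_atoms_same_mark(self, benzene):
        g = perceive_rings(benzene)
        assert len({mna_atom_mark(g, i) for i in range(6)}) == 1


class TestMnaDescriptors:
    def test_methane_level0(self, methane):
        counts = mna_descriptors(prepared(methane), max_level=0)
        assert dict(counts) == {"-C": 1, "-H": 4}

    def test_methane_level1_carbon(self, methane):
        counts = mna_descriptors(prepared(methane), max_level=1)
        assert counts["-C(-H-H-H-H)"] == 1
        assert counts["-H(-C)"] == 4

    def test_level0_multiplicity_equals_atom_count(self, fixture_graphs):
        for g in fixture_graphs:
            gp = prepared(g)
            counts = mna_descriptors(gp, max_level=0)
            assert sum(counts.values()) == gp.n_atoms

    def test_permutation_invariance(self, fixture_graphs):
        rng = np.random.default_rng(0)
        for g in fixture_graphs:
            base = mna_descriptors(prepared(g), 2)
            for _ in range(5):
                gp = permute_graph(g, rng)
                assert mna_descriptors(prepared(gp), 2) == base

    def test_total_multiplicity_per_level(self, benzene):
        gp = prepared(benzene)
        counts = mna_descriptors(gp, max_level=2)
        assert sum(counts.values()) == 3 * gp.n_atoms

    def test_negative_level_rejected(self, methane):
        with pytest.raises(ValueError):
            mna_descriptors(prepared(methane), max_level=-1)


class TestVocabulary:
    def test_methane_level1_vocabulary(self, methane):
        voc = build_vocabulary([mna_descriptors(prepared(methane), 1)])
        assert voc == sorted(["-C", "-H", "-C(-H-H-H-H)", "-H(-C)"])

    def test_monotone_in_input(self, fixture_graphs):
        sets = [mna_descriptors(prepared(g), 2) for g in fixture_graphs]
        small = set(build_vocabulary(sets[:4]))
        assert small <= set(build_vocabulary(sets))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])


def series_expm(a: np.ndarray, terms: int = 80) -> np.ndarray:
    """Independent Taylor-series matrix exponential (oracle)."""
    out = np.eye(len(a))
    term = np.eye(len(a))
    for k in range(1, terms):
        term = term @ a / k
        out = out + term
    return out


def qna_oracle(graph, props):
    heavy = graph.heavy_indices()
    pos = {a: k for k, a in enumerate(heavy)}
    adj = np.zeros((len(heavy), len(heavy)))
    for b in graph.bonds:
        if b.i in pos and b.j in pos:
            adj[pos[b.i], pos[b.j]] = adj[pos[b.j], pos[b.i]] = 1.0
    ip = np.array([props[graph.atoms[a].element].ip_ev for a in heavy])
    ea = np.array([props[graph.atoms[a].element].ea_ev for a in heavy])
    b_vec = ip - ea
    d = np.diag(1.0 / np.sqrt(b_vec))
    m = d @ series_expm(-0.5 * adj) @ d
    return m.sum(axis=1), m @ (0.5 * (ip + ea))


class TestQnaValues:
    def test_single_atom_closed_form(self, methane, props):
        pt = qna_values(methane, props)[0]
        e = props["C"]
        b, a = e.ip_ev - e.ea_ev, 0.5 * (e.ip_ev + e.ea_ev)
        assert pt.p == pytest.approx(1.0 / b, abs=1e-12)
        assert pt.q == pytest.approx(a / b, abs=1e-12)

    def test_homonuclear_diatomic_closed_form(self, props):
        g = MolecularGraph(atoms=[Atom("C"), Atom("C")], bonds=[Bond(0, 1, 1)])
        e = props["C"]
        b, a = e.ip_ev - e.ea_ev, 0.5 * (e.ip_ev + e.ea_ev)
        for pt in qna_values(g, props):
            # exp(-C/2) = cosh(1/2) I - sinh(1/2) C; row sum = e^{-1/2}
            assert pt.p == pytest.approx(np.exp(-0.5) / b, abs=1e-12)
            assert pt.q == pytest.approx(a * pt.p, abs=1e-12)

    def test_matches_series_oracle_on_fixtures(self, fixture_graphs, props):
        for g in fixture_graphs:
            pts = qna_values(g, props)
            p_ref, q_ref = qna_oracle(g, props)
            assert np.allclose([pt.p for pt in pts], p_ref, atol=1e-10)
            assert np.allclose([pt.q for pt in pts], q_ref, atol=1e-10)

    def test_permutation_gives_same_multiset(self, fixture_graphs, props):
        rng = np.random.default_rng(1)
        for g in fixture_graphs:
            base = sorted((round(pt.p, 12), round(pt.q, 12)) for pt in qna_values(g, props))
            gp = permute_graph(g, rng)
            permuted = sorted((round(pt.p, 12), round(pt.q, 12)) for pt in qna_values(gp, props))
            assert permuted == base

    def test_missing_element_named(self, props):
        g = MolecularGraph(atoms=[Atom("Se")], bonds=[])
        with pytest.raises(KeyError, match="Se"):
            qna_values(g, props)


class TestQnaFeatures:
    def test_degree_zero_is_unit(self, benzene, props):
        feats = qna_features(qna_values(benzene, props), degree=0)
        assert feats.tolist() == [1.0]

    def test_single_atom_degree_one_layout(self, methane, props):
        pts = qna_values(methane, props)
        scaling = QNAScaling(p_min=0.0, p_max=1.0, q_min=0.0, q_max=1.0)
        p_hat, q_hat = scaling.apply(pts)
        feats = qna_features(pts, degree=1, scaling=scaling)
        expect = [1.0, q_hat[0], p_hat[0], p_hat[0] * q_hat[0]]
        assert feats == pytest.approx(expect)

    def test_invariant_to_atom_order(self, fixture_graphs, props):
        rng = np.random.default_rng(2)
        scaling = QNAScaling.fit([qna_values(g, props) for g in fixture_graphs])
        for g in fixture_graphs:
            base = qna_features(qna_values(g, props), 3, scaling)
            gp = permute_graph(g, rng)
            assert qna_features(qna_values(gp, props), 3, scaling) == pytest.approx(base.tolist())


class TestWholeMolecule:
    def test_single_atom_length_zero(self, methane):
        assert topological_length(methane) == 0

    def test_chain_length(self):
        g = lq.read_structures("CCCCC", "smiles")[0]
        assert topological_length(g) == 4

    def test_cyclohexane_diameter_three(self):
        g = lq.read_structures("C1CCCCC1", "smiles")[0]
        assert topological_length(g) == 3

    def test_disconnected_rejected(self):
        g = MolecularGraph(atoms=[Atom("C"), Atom("C")], bonds=[])
        with pytest.raises(ValueError, match="disconnected"):
            topological_length(g)

    def test_volume_monotone_in_size(self, props):
        methane = lq.read_structures("C", "smiles")[0]
        ethane = lq.read_structures("CC", "smiles")[0]
        assert topological_volume(ethane, props) > topological_volume(methane, props)

    def test_volume_is_sphere_sum(self, props):
        g = lq.read_structures("CO", "smiles")[0]
        expect = (4 / 3) * np.pi * (props["C"].r_cov_a ** 3 + props["O"].r_cov_a ** 3)
        assert topological_volume(g, props) == pytest.approx(expect)

    def test_lipophilicity_hand_sum_propane(self, props):
        g = lq.read_structures("CCC", "smiles")[0]
        assert lipophilicity(g, props) == pytest.approx(3 * props["C"].logp_contrib)

    def test_lipophilicity_additive_under_extension(self, props):
        short = lq.read_structures("OCC", "smiles")[0]
        long = lq.read_structures("OCCCC", "smiles")[0]
        # appending two carbons adds exactly two positive C contributions
        assert lipophilicity(long, props) - lipophilicity(short, props) == pytest.approx(
            2 * props["C"].logp_contrib
        )


class TestFeaturizer:
    def test_matrix_shapes_and_columns(self, fixture_graphs):
        fz = Featurizer().fit(fixture_graphs)
        Xq = fz.transform(fixture_graphs, "QNA")
        Xm = fz.transform(fixture_graphs, "MNA")
        assert Xq.shape == (len(fixture_graphs), 16 + 3)
        assert list(Xq.columns[-3:]) == ["top_length", "top_volume", "lipophilicity"]
        assert set(Xm.columns[:-3]) == set(fz.vocabulary)

    def test_roundtrip_serialization(self, fixture_graphs):
        fz = Featurizer().fit(fixture_graphs)
        fz2 = Featurizer.from_dict(fz.to_dict())
        X1 = fz.transform(fixture_graphs, "MNA")
        X2 = fz2.transform(fixture_graphs, "MNA")
        assert (X1.to_numpy() == X2.to_numpy()).all()
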