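"""Tokenizer, attribute codes, hydrogen-suppressed graph, Morgan EC."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcqsar.chem import (
    FeatureConfig,
    SmilesError,
    atom_attributes,
    atom_code,
    attribute_kind,
    build_hsg,
    extract_features,
    graph_attributes,
    graph_code,
    morgan_ec,
    pair_attributes,
    pair_code,
    tokenize_smiles,
)


class TestTokenizer:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("Clc1ccccc1", ["Cl", "c", "1", "c", "c", "c", "c", "c", "1"]),
            ("O", ["O"]),
            ("C%11CC%11", ["C", "%11", "C", "C", "%11"]),
            ("CC(=O)O", ["C", "C", "(", "=", "O", ")", "O"]),
            ("[NH4+]", ["[NH4+]"]),
            ("C[C@H](N)C", ["C", "[C@H]", "(", "N", ")", "C"]),
            ("BrCCBr", ["Br", "C", "C", "Br"]),
            ("C/C=C\\C", ["C", "/", "C", "=", "C", "\\", "C"]),
        ],
    )
    def test_examples(self, smiles, expected):
        assert tokenize_smiles(smiles) == expected

    def test_round_trip_over_corpus(self, smiles_corpus):
        for s in smiles_corpus:
            assert "".join(tokenize_smiles(s)) == s

    @pytest.mark.parametrize(
        "bad",
        ["", "C(C", "C)C", "C[NH", "C]C", "C%1", "C%", "C1CC", "c1ccccc2", "C C", "C$C"],
    )
    def test_malformed_rejected(self, bad):
        with pytest.raises(SmilesError):
            tokenize_smiles(bad)

    def test_error_carries_position(self):
        with pytest.raises(SmilesError) as exc:
            tokenize_smiles("CC%2C")
        assert exc.value.position == 2

    def test_ring_label_reuse_is_valid(self):
        # digit 1 closes, then reopens for the second ring
        tokens = tokenize_smiles("C1CC1CC1CC1")
        assert tokens.count("1") == 4


class TestAttributeCodes:
    def test_atom_code_format(self):
        assert atom_code("C") == "C..........."
        assert atom_code("Cl") == "Cl.........."
        assert atom_code("%11") == "%11........."

    def test_pair_canonicalization_symmetry(self):
        assert pair_code("O", "C") == pair_code("C", "O") == "O...C......."
        assert pair_code("c", "1") == pair_code("1", "c") == "c...1......."

    @pytest.mark.parametrize(
        "a,b,code",
        [
            # codes as printed in published promoter tables: the larger
            # token (descending lexicographic) occupies the first field
            ("O", "(", "O...(......."),
            ("1", "(", "1...(......."),
            ("=", "(", "=...(......."),
            ("c", "F", "c...F......."),
            ("C", "=", "C...=......."),
            ("n", "(", "n...(......."),
            ("O", "=", "O...=......."),
            ("c", "C", "c...C......."),
        ],
    )
    def test_pair_field_order_matches_published_codes(self, a, b, code):
        assert pair_code(a, b) == code
        assert pair_code(b, a) == code

    def test_atom_and_pair_multiset_sizes(self, smiles_corpus):
        for s in smiles_corpus:
            tokens = tokenize_smiles(s)
            assert sum(atom_attributes(tokens).values()) == len(tokens)
            assert sum(pair_attributes(tokens).values()) == len(tokens) - 1

    def test_pair_attributes_example(self):
        assert set(pair_attributes(["C", "=", "O"])) == {"C...=.......", "O...=......."}

    def test_empty_and_single(self):
        assert atom_attributes([]) == {}
        assert pair_attributes(["O"]) == {}

    def test_code_format_regexes(self, smiles_corpus):
        atom_re = re.compile(r"^[^.\s]{1,4}\.*$")
        pair_re = re.compile(r"^[^.\s]{1,4}\.*[^.\s]{1,4}\.*$")
        for s in smiles_corpus:
            feats = extract_features(s, FeatureConfig(graph_orders=frozenset({0})))
            for code in feats:
                kind = attribute_kind(code)
                assert len(code) == 12
                if kind == "atom":
                    assert atom_re.match(code), code
                    assert code[4:] == "." * 8
                elif kind == "pair":
                    assert pair_re.match(code), code
                else:
                    assert code.startswith("EC")

    def test_aromatic_distinct_from_aliphatic(self):
        assert atom_code("c") != atom_code("C")


class TestGraph:
    def test_linear_chain(self):
        g = build_hsg("CCO")
        assert g.vertices == ["C", "C", "O"]
        assert g.edges == [(0, 1), (1, 2)]

    def test_benzene_ring_closure(self):
        g = build_hsg("c1ccccc1")
        assert g.vertices == ["C"] * 6
        assert len(g.edges) == 6
        assert sorted(len(nb) for nb in g.adjacency()) == [2] * 6

    def test_branch_star(self):
        g = build_hsg("CC(C)C")
        degrees = [len(nb) for nb in g.adjacency()]
        assert sorted(degrees) == [1, 1, 1, 3]

    def test_unmatched_ring_rejected(self):
        with pytest.raises(SmilesError):
            build_hsg("C1CC")

    def test_hydrogens_suppressed_in_brackets(self):
        g = build_hsg("C[NH3+]")
        assert g.vertices == ["C", "N"]

    def test_percent_ring_label(self):
        g = build_hsg("C%11CCCC%11")
        assert len(g.edges) == 5  # 4 chain + 1 closure

    def test_against_rdkit_oracle(self, smiles_corpus):
        """Vertex count, edge count and degree multiset agree with RDKit
        on every chemically valid corpus entry."""
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem

        checked = 0
        for s in smiles_corpus:
            mol = Chem.MolFromSmiles(s)
            if mol is None:
                continue
            g = build_hsg(s)
            assert len(g.vertices) == mol.GetNumAtoms(), s
            assert len(g.edges) == mol.GetNumBonds(), s
            want = sorted(a.GetDegree() for a in mol.GetAtoms())
            assert sorted(len(nb) for nb in g.adjacency()) == want, s
            checked += 1
        assert checked >= 30


class TestMorgan:
    def test_order0_is_degree(self):
        g = build_hsg("CCO")
        assert morgan_ec(g, 0) == [1, 2, 1]

    def test_order1_sums_neighbor_degrees(self):
        g = build_hsg("CCO")
        assert morgan_ec(g, 1) == [2, 2, 2]

    def test_single_vertex(self):
        g = build_hsg("O")
        assert morgan_ec(g, 0) == [0]
        assert morgan_ec(g, 3) == [0]

    @given(st.integers(0, 3), st.randoms(use_true_random=False))
    @settings(max_examples=25, deadline=None)
    def test_relabelling_invariance(self, order, rnd):
        """Morgan values follow the vertex under any relabelling."""
        from mcqsar.chem import MolecularGraph

        g = build_hsg("CC(=O)Oc1ccccc1C(N)C")
        n = len(g.vertices)
        perm = list(range(n))
        rnd.shuffle(perm)
        g2 = MolecularGraph(
            vertices=[g.vertices[perm.index(i)] for i in range(n)],
            edges=[(perm[a], perm[b]) for a, b in g.edges],
        )
        base = morgan_ec(g, order)
        permuted = morgan_ec(g2, order)
        assert [permuted[perm[i]] for i in range(n)] == base


class TestGraphAttributes:
    def test_path_order0(self):
        g = build_hsg("CCO")
        feats = graph_attributes(g, {0})
        assert feats == {
            graph_code(0, "C", 1): 1,
            graph_code(0, "C", 2): 1,
            graph_code(0, "O", 1): 1,
        }

    def test_empty_orders(self):
        assert graph_attributes(build_hsg("CCO"), set()) == {}

    def test_benzene_all_equivalent(self):
        feats = graph_attributes(build_hsg("c1ccccc1"), {0})
        assert feats == {graph_code(0, "C", 2): 6}

    def test_hybrid_config_extends_feature_multiset(self):
        plain = extract_features("CCO")
        hybrid = extract_features("CCO", FeatureConfig(graph_orders=frozenset({0, 1})))
        assert set(plain) < set(hybrid)
        assert sum(hybrid.values()) == sum(plain.values()) + 2 * 3
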