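import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mulrecon.simulate import SimConfig, random_binary_tree, simulate_dataset
from mulrecon.treeio import (
    LeafLabelScheme,
    NewickParseError,
    PruneError,
    Role,
    RootingError,
    SpeciesMap,
    TreeError,
    canonical_form,
    isomorphic,
    parse_newick,
    prune_to,
    resolve_polytomies,
    root_by_outgroup,
    write_newick,
)

from conftest import gene_tree


class TestParse:
    def test_three_leaf_structure(self):
        t = parse_newick("((A,B),C);")
        assert t.n_leaves == 3
        kids = t.root.children
        assert len(kids) == 2
        assert sorted(l.label for l in t.leaves()) == ["A", "B", "C"]
        # one root child is the (A,B) clade, the other the leaf C
        ab = t.find_clade({"A", "B"})
        assert ab.parent is t.root

    def test_eight_taxon_sampling(self):
        t = parse_newick("(O,((o1,(o2,o3)),(c1,(c2,(c3,c4)))));")
        assert t.n_leaves == 8
        assert t.is_binary()

    def test_multifurcation_rejected_when_disallowed(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B,C),D);", allow_multifurcations=False)
        t = parse_newick("((A,B,C),D);")
        assert not t.is_binary()

    @pytest.mark.parametrize(
        "bad", ["((A,B),C;", "(A,(B,C)));", "", "(,A);", "(A,B)"]
    )
    def test_malformed_input_reports_offset(self, bad):
        with pytest.raises(NewickParseError) as exc:
            parse_newick(bad)
        assert exc.value.offset >= 0

    def test_duplicate_leaves_rejected_for_species_trees(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_newick("((A,A),B);", require_unique_leaves=True)

    def test_branch_lengths_and_internal_labels_ignored(self):
        t = parse_newick("((A:0.1,B:0.2)90:0.05,C:1e-3)root;")
        assert write_newick(t) == "((A,B),C);"


class TestWrite:
    def test_single_leaf(self):
        assert write_newick(parse_newick("A;")) == "A;"

    def test_round_trip_is_isomorphic(self):
        t = parse_newick("((A,B),C);")
        assert isomorphic(t, parse_newick(write_newick(t)))

    def test_round_trip_1000_random_trees(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(10)]
        for _ in range(1000):
            t = random_binary_tree(labels, rng)
            assert canonical_form(parse_newick(write_newick(t))) == canonical_form(t)

    def test_round_trip_against_dendropy(self):
        """Independent parser oracle: dendropy must read our output and
        agree on the labeled topology."""
        import dendropy

        rng = np.random.default_rng(3)
        labels = [f"x{i}" for i in range(8)]
        for _ in range(25):
            t = random_binary_tree(labels, rng)
            dt = dendropy.Tree.get(
                data=write_newick(t), schema="newick", preserve_underscores=True
            )
            back = parse_newick(
                dt.as_string(schema="newick", suppress_rooting=True,
                             suppress_edge_lengths=True)
            )
            assert isomorphic(back, t)


class TestRooting:
    def test_outgroup_separated(self):
        t = root_by_outgroup(parse_newick("((A,B),(C,O));"), "O")
        leafsets = [
            frozenset(l.species_or_label() for l in _leaves(c)) for c in t.root.children
        ]
        assert frozenset({"O"}) in leafsets
        assert frozenset({"A", "B", "C"}) in leafsets

    def test_non_monophyletic_outgroup_raises(self):
        g = gene_tree("((a,o1),(b,o2));")
        with pytest.raises(RootingError):
            root_by_outgroup(g, "O")

    def test_missing_outgroup_raises(self):
        with pytest.raises(RootingError):
            root_by_outgroup(parse_newick("(A,B);"), "O")

    def test_rooting_is_idempotent(self):
        t1 = root_by_outgroup(parse_newick("((A,B),(C,O));"), "O")
        t2 = root_by_outgroup(t1, "O")
        assert isomorphic(t1, t2)

    def test_simulated_families_recover_true_root_split(self):
        """Without topological error, outgroup rooting must recover the
        simulator's root bipartition (outgroup vs everything else)."""
        cfg = SimConfig(n_families=200, seed=3, nni_prob=0.0)
        trees, _ = simulate_dataset(cfg)
        assert len(trees) == 200
        for t in trees:
            og_sides = [
                frozenset(l.species for l in _leaves(c)) for c in t.root.children
            ]
            assert frozenset({"OUT"}) in og_sides


def _leaves(node):
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


class TestPrune:
    def test_basic(self):
        assert write_newick(prune_to(parse_newick("((A,B),C);"), {"A", "C"})) == "(A,C);"

    def test_reference_topology_to_first_sampling(self):
        full = parse_newick(
            "((OUT2,OUT),((x1,(a1,(a2,a3))),(b1,(b2,(b3,b4)))));"
        )
        pruned = prune_to(full, {"OUT", "a1", "a2", "a3", "b1", "b2", "b3", "b4"})
        expect = parse_newick("(OUT,((a1,(a2,a3)),(b1,(b2,(b3,b4)))));")
        assert isomorphic(pruned, expect)

    def test_single_species(self):
        assert write_newick(prune_to(parse_newick("((A,B),C);"), {"B"})) == "B;"

    def test_empty_intersection_raises(self):
        with pytest.raises(PruneError):
            prune_to(parse_newick("(A,B);"), {"Z"})

    def test_idempotent(self):
        t = parse_newick("((A,(B,D)),C);")
        once = prune_to(t, {"A", "B", "C"})
        twice = prune_to(once, {"A", "B", "C"})
        assert isomorphic(once, twice)


class TestLabelSchemeAndMap:
    def test_scheme_split_join(self):
        s = LeafLabelScheme()
        assert s.split("sp1@g7") == ("sp1", "g7")
        assert s.join("sp1", "g7") == "sp1@g7"
        with pytest.raises(TreeError):
            s.split("nodelimiter")
        with pytest.raises(TreeError):
            s.split("@gene")

    def test_suffix_scheme(self):
        s = LeafLabelScheme(delimiter="_", species_first=False)
        assert s.split("g7_sp1") == ("sp1", "g7")

    def test_species_map_roundtrip(self, tmp_path):
        sm = SpeciesMap({"O": Role.OUTGROUP, "a": Role.CLADE_A, "b": Role.CLADE_B})
        p = tmp_path / "map.tsv"
        sm.write_tsv(p)
        back = SpeciesMap.read_tsv(p)
        assert back.roles == sm.roles
        assert back.outgroup == "O"
        assert back.focal == {"a", "b"}

    def test_bad_role_rejected(self):
        with pytest.raises(ValueError):
            SpeciesMap({"x": "ingroup"})

    def test_two_outgroups_rejected(self):
        sm = SpeciesMap({"O1": Role.OUTGROUP, "O2": Role.OUTGROUP})
        with pytest.raises(ValueError):
            sm.outgroup


def test_resolve_polytomies_binarizes(rng):
    t = parse_newick("((A,B,C,D),(E,F,G));")
    b = resolve_polytomies(t, rng)
    assert b.is_binary()
    assert sorted(b.leaf_labels()) == sorted(t.leaf_labels())


@given(
    st.lists(
        st.text(alphabet="abcdefgh", min_size=1, max_size=4),
        min_size=1,
        max_size=8,
        unique=True,
    ),
    st.integers(0, 2**31 - 1),
)
def test_round_trip_property(labels, seed):
    t = random_binary_tree(labels, np.random.default_rng(seed))
    assert canonical_form(parse_newick(write_newick(t))) == canonical_form(t)
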