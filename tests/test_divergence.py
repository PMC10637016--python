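"""Pairwise alignment, K2P distances, neighbor joining and bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitomine.core import ValidationError
from mitomine.divergence import (
    DistanceMatrix,
    PairCounts,
    bootstrap_support,
    count_substitutions,
    distance_matrix,
    k2p_distance,
    k2p_from_pq,
    nj_tree,
    pairwise_align,
)
from mitomine.published import macrobrachium_k2p_matrix
from mitomine.synth import (
    GenomeLayout,
    MutationModel,
    RegionSpec,
    build_reference,
    evolve_genome,
)


class TestPairwiseAlign:
    def test_identical_sequences_gapless(self):
        a, b = pairwise_align("ACGTACGT", "ACGTACGT")
        assert a == b == "ACGTACGT"

    def test_single_gap_column(self):
        a, b = pairwise_align("ACGT", "ACT")
        assert len(a) == 4 and len(b) == 4
        assert b.count("-") == 1
        matches = sum(x == y for x, y in zip(a, b) if x != "-" and y != "-")
        assert matches == 3

    def test_score_matches_dp_oracle_on_random_pairs(self):
        from oracles import local_alignment_score
        from mitomine.mining import MiningParams

        # global vs local oracle agree when a high-identity overlap spans
        # both sequences; use mutated full-length copies
        rng = np.random.default_rng(77)
        aligner = MiningParams().global_aligner()
        for _ in range(10):
            n = int(rng.integers(200, 1000))
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            b = list(a)
            for i in range(n):
                if rng.random() < 0.03:
                    b[i] = "ACGT"[int(rng.integers(4))]
            b = "".join(b)
            assert aligner.align(a, b).score == local_alignment_score(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_align("", "ACGT")


class TestCountSubstitutions:
    @pytest.mark.parametrize(
        "a,b,n,s,v",
        [
            ("AG", "GG", 2, 1, 0),
            ("AC", "CA", 2, 0, 2),
            ("A-", "AT", 1, 0, 0),
            ("ACGT", "ACGT", 4, 0, 0),
            ("ANGT", "ACGT", 3, 0, 0),
        ],
    )
    def test_examples(self, a, b, n, s, v):
        c = count_substitutions(a, b)
        assert (c.n, c.s, c.v) == (n, s, v)

    def test_all_gap_columns_rejected(self):
        with pytest.raises(ValidationError):
            count_substitutions("--", "AT")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=100))
    def test_counts_match_naive_classification(self, a):
        rng = np.random.default_rng(len(a))
        b = "".join(
            "ACGT"[int(rng.integers(4))] if rng.random() < 0.3 else ch
            for ch in a
        )
        c = count_substitutions(a, b)
        ts = {"AG", "GA", "CT", "TC"}
        s = sum(1 for x, y in zip(a, b) if x != y and x + y in ts)
        v = sum(1 for x, y in zip(a, b) if x != y and x + y not in ts)
        assert (c.n, c.s, c.v) == (len(a), s, v)


class TestK2P:
    def test_zero_distance(self):
        assert k2p_from_pq(0.0, 0.0) == 0.0
        a = "ACGT" * 20
        assert k2p_distance(count_substitutions(a, a)) == 0.0

    def test_closed_form_grid(self):
        """Independent evaluation of d = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
        for P in (0.0, 0.05, 0.1, 0.2, 0.3):
            for Q in (0.0, 0.05, 0.1, 0.2):
                if 1 - 2 * P - Q <= 0:
                    continue
                expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(
                    1 - 2 * Q
                )
                assert k2p_from_pq(P, Q) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_reference_value(self):
        assert k2p_from_pq(0.2, 0.1) == pytest.approx(0.4024, abs=5e-5)

    def test_undefined_domain_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(k2p_from_pq(0.45, 0.2))
        with pytest.warns(UserWarning):
            assert math.isnan(k2p_from_pq(0.1, 0.55))

    def test_monotone_in_p_and_q(self):
        grid = np.linspace(0.0, 0.2, 9)
        for q in grid:
            d = [k2p_from_pq(p, q) for p in grid]
            assert all(x < y for x, y in zip(d, d[1:]))
        for p in grid:
            d = [k2p_from_pq(p, q) for q in grid]
            assert all(x < y for x, y in zip(d, d[1:]))


def _pair_layout(n=10000):
    return GenomeLayout(
        regions=[RegionSpec("rrn", "rRNA", n, "L"),
                 RegionSpec("ctl", "control", 100, "L")]
    )


class TestDistanceMatrix:
    def test_duplicate_taxa_distance_zero(self, reference):
        a = reference.copy()
        a.name = "a"
        b = reference.copy()
        b.name = "b"
        c = evolve_genome(reference, MutationModel(0.1, seed=3))
        c.name = "c"
        m = distance_matrix([a, b, c], mode="whole")
        assert m.get("a", "b") == 0.0
        assert m.get("a", "c") > 0.0
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)

    def test_pair_recovers_simulated_divergence(self):
        g = build_reference(_pair_layout(), seed=21)
        ev = evolve_genome(g, MutationModel(d_sim=0.2, kappa=2.0, seed=22))
        ev.name = "evolved"
        twin = g.copy()
        twin.name = "twin"
        m = distance_matrix([g, ev, twin], mode="whole")
        assert m.values[0, 1] == pytest.approx(0.2, abs=0.02)

    def test_whole_mode_truncates_at_control(self, reference):
        ctl = reference.feature("D-loop")
        from mitomine.divergence import _extract_sequences

        _, seqs = _extract_sequences([reference], "whole", None)
        assert len(seqs[0]) == ctl.start - 1

    def test_gene_mode_missing_gene_undefined(self, reference):
        a = reference.copy()
        a.name = "a"
        b = reference.copy()
        b.name = "b"
        b.features = [f for f in b.features if f.name != "COI"]
        c = reference.copy()
        c.name = "c"
        m = distance_matrix([a, b, c], mode="gene", gene="COI")
        assert math.isnan(m.get("a", "b"))
        assert m.get("a", "c") == 0.0
        assert m.undefined_pairs() == [("a", "b"), ("b", "c")]


class TestNJ:
    def test_fewer_than_three_taxa_rejected(self):
        m = DistanceMatrix(labels=["a", "b"],
                           values=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError, match="at least 3"):
            nj_tree(m)

    def test_undefined_entries_rejected(self):
        v = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]], float)
        m = DistanceMatrix(labels=list("abc"), values=v)
        with pytest.raises(ValidationError, match="undefined"):
            nj_tree(m)

    def test_additive_quartet_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        labels = list("ABCD")
        vals = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            dtype=float,
        )
        m = DistanceMatrix(labels=labels, values=vals)
        tree = nj_tree(m)
        assert tree.siblings("A", "B")
        newick = tree.to_newick(include_support=False)
        assert "A:1.000000000" in newick and "B:2.000000000" in newick
        assert "C:3.000000000" in newick and "D:4.000000000" in newick

    def test_quartet_split_agrees_with_four_point_oracle(self):
        from oracles import quartet_splits

        rng = np.random.default_rng(5)
        for _ in range(20):
            # random additive quartet: internal w, limbs la..ld
            la, lb, lc, ld, w = rng.uniform(0.1, 2.0, 5)
            labels = list("ABCD")
            d = {
                ("A", "B"): la + lb, ("C", "D"): lc + ld,
                ("A", "C"): la + w + lc, ("A", "D"): la + w + ld,
                ("B", "C"): lb + w + lc, ("B", "D"): lb + w + ld,
            }

            def dist(x, y):
                return d.get((x, y)) or d.get((y, x)) or 0.0

            vals = np.array(
                [[dist(x, y) for y in labels] for x in labels]
            )
            tree = nj_tree(DistanceMatrix(labels=labels, values=vals))
            best = quartet_splits(labels, dist)[0][1]
            expected_pairs = [tuple(sorted(p)) for p in best]
            assert tree.siblings(*expected_pairs[0])
            assert tree.siblings(*expected_pairs[1])

    def test_random_additive_six_taxon_topology_recovered(self):
        import dendropy

        rng = np.random.default_rng(11)
        for trial in range(5):
            taxa = [f"t{i}" for i in range(6)]
            tns = dendropy.TaxonNamespace(taxa)
            src = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=6,
                rng=__import__("random").Random(100 + trial),
            )
            for e in src.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(rng.uniform(0.2, 2.0))
            pdm = src.phylogenetic_distance_matrix()
            labels = sorted(t.label for t in tns)
            tx = {t.label: t for t in tns}
            vals = np.array(
                [
                    [
                        0.0 if a == b
                        else pdm.patristic_distance(tx[a], tx[b])
                        for b in labels
                    ]
                    for a in labels
                ]
            )
            tree = nj_tree(DistanceMatrix(labels=labels, values=vals))
            src.encode_bipartitions()
            expected = set()
            ref = labels[0]
            all_set = frozenset(labels)
            for node in src.preorder_node_iter():
                if node.parent_node is None or node.is_leaf():
                    continue
                side = frozenset(
                    lf.taxon.label for lf in node.leaf_iter()
                )
                if ref in side:
                    side = all_set - side
                if 2 <= len(side) <= 4:
                    expected.add(side)
            assert tree.bipartitions() == expected

    def test_published_matrix_recovers_reported_groups(self):
        tree = nj_tree(macrobrachium_k2p_matrix())
        assert tree.siblings(
            "M. rosenbergii AY659990.1", "M. rosenbergii KY865098.1"
        )
        assert tree.siblings(
            "M. nipponense HQ830201.1", "M. bullatum KM978918.1"
        )

    def test_negative_branch_length_clamped(self, caplog):
        vals = np.array(
            [
                [0.0, 0.1, 0.4, 0.4],
                [0.1, 0.0, 0.4, 0.45],
                [0.4, 0.4, 0.0, 0.02],
                [0.4, 0.45, 0.02, 0.0],
            ]
        )
        m = DistanceMatrix(labels=list("abcd"), values=vals)
        with caplog.at_level("WARNING"):
            tree = nj_tree(m)
        assert ":-" not in tree.to_newick()


def _quartet_seqs(seed=0, n=4000, internal=0.15, limb=0.02):
    layout = _pair_layout(n)
    root = build_reference(layout, seed=seed)
    left = evolve_genome(root, MutationModel(internal / 2, seed=seed + 1))
    right = evolve_genome(root, MutationModel(internal / 2, seed=seed + 2))
    taxa = {
        "A": evolve_genome(left, MutationModel(limb, seed=seed + 3)),
        "B": evolve_genome(left, MutationModel(limb, seed=seed + 4)),
        "C": evolve_genome(right, MutationModel(limb, seed=seed + 5)),
        "D": evolve_genome(right, MutationModel(limb, seed=seed + 6)),
    }
    return [taxa[k].seq for k in "ABCD"], list("ABCD")


class TestBootstrap:
    def test_identity_replicate_gives_full_support(self):
        seqs, labels = _quartet_seqs(seed=40)
        tree = bootstrap_support(seqs, labels, b=1, seed=0, resample=False)
        supports = [n.support for n in tree._edge_nodes()]
        assert supports and all(s == 100.0 for s in supports)

    def test_clean_quartet_high_support(self):
        seqs, labels = _quartet_seqs(seed=41)
        tree = bootstrap_support(seqs, labels, b=100, seed=7)
        assert tree.siblings("C", "D") or tree.siblings("A", "B")
        supports = [n.support for n in tree._edge_nodes()]
        assert min(supports) >= 95.0

    def test_deterministic_under_seed(self):
        seqs, labels = _quartet_seqs(seed=42)
        t1 = bootstrap_support(seqs, labels, b=50, seed=3)
        t2 = bootstrap_support(seqs, labels, b=50, seed=3)
        assert t1.to_newick() == t2.to_newick()
        t3 = bootstrap_support(seqs, labels, b=50, seed=4)
        assert t3.to_newick() != "" # different seed still valid tree
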