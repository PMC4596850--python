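import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from venomest import phylo
from venomest.phylo import (
    DistanceMatrix,
    FamilyAssignment,
    bootstrap_support,
    classify_families,
    cross_species_report,
    distance_matrix,
    global_align,
    nj_tree,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_score(a, b, match, mismatch, gap):
    """Enumerate every global alignment recursively (no memoization)."""
    best = [-float("inf")]

    def walk(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1,
                 score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            walk(i + 1, j, score + gap)
        if j < len(b):
            walk(i, j + 1, score + gap)

    walk(0, 0, 0.0)
    return best[0]


class TestGlobalAlign:
    def test_identical(self):
        aln = global_align("ACDEF", "ACDEF")
        assert aln.identity == 1.0

    def test_single_mismatch(self):
        aln = global_align("ACDEFG", "ACDEYG")
        assert aln.identity == pytest.approx(5 / 6)
        assert aln.score == brute_force_score("ACDEFG", "ACDEYG", 1, -1, -2)

    def test_completely_different(self):
        assert global_align("A", "G").identity == 0.0

    def test_gap_handling(self):
        aln = global_align("ACDEF", "ACEF")
        assert "-" in aln.aligned_b
        assert aln.aligned_a.replace("-", "") == "ACDEF"
        assert aln.aligned_b.replace("-", "") == "ACEF"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")

    def test_score_consistent_with_alignment(self):
        aln = global_align("WCKDE", "WKDEF")
        rescore = sum(
            -2.0 if "-" in (x, y) else (1.0 if x == y else -1.0)
            for x, y in zip(aln.aligned_a, aln.aligned_b)
        )
        assert rescore == aln.score

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACDE", min_size=1, max_size=6),
           st.text(alphabet="ACDE", min_size=1, max_size=6))
    def test_equals_brute_force(self, a, b):
        assert global_align(a, b).score == brute_force_score(a, b, 1, -1, -2)


class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        dm = distance_matrix([("a", "WCK"), ("b", "WCK"), ("c", "WCK")])
        assert np.allclose(dm.values, 0.0)

    def test_disjoint_near_one(self):
        dm = distance_matrix([("a", "WWWW"), ("b", "KKKK"), ("c", "DDDD")])
        off = dm.values[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0)

    def test_duplicate_ids_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix([("a", "WK"), ("a", "WD"), ("b", "WC")])

    def test_monotone_with_substitutions(self, rng):
        base = "".join(AA[i] for i in rng.integers(0, 20, 60))
        variants = [("v0", base)]
        seq = list(base)
        for k in range(1, 4):
            for _ in range(6):
                pos = int(rng.integers(len(seq)))
                seq[pos] = AA[(AA.index(seq[pos]) + 1) % 20]
            variants.append((f"v{k}", "".join(seq)))
        dm = distance_matrix(variants)
        d = [dm.get("v0", f"v{k}") for k in range(1, 4)]
        assert d[0] < d[1] < d[2]

    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))


def random_additive_matrix(n_taxa, seed):
    """Random binary tree with positive branch lengths -> path metric.

    Returns (labels, matrix, splits of the generating tree).
    """
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a star of 3, attach remaining leaves to random edges
    nodes = {i: labels[i] for i in range(n_taxa)}
    edges = []  # (u, v, length)
    next_id = [n_taxa]

    def new_internal():
        nid = next_id[0]
        next_id[0] += 1
        return nid

    center = new_internal()
    for i in range(3):
        edges.append([i, center, float(rng.uniform(0.5, 3.0))])
    for leaf in range(3, n_taxa):
        k = int(rng.integers(len(edges)))
        u, v, length = edges.pop(k)
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8))
        edges.append([u, mid, length * split])
        edges.append([mid, v, length * (1 - split)])
        edges.append([leaf, mid, float(rng.uniform(0.5, 3.0))])

    # all-pairs path lengths over the tree
    adj = {}
    for u, v, length in edges:
        adj.setdefault(u, []).append((v, length))
        adj.setdefault(v, []).append((u, length))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, length in adj[node]:
                if nb not in out:
                    out[nb] = out[node] + length
                    stack.append(nb)
        return out

    mat = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        d = dists_from(i)
        for j in range(n_taxa):
            mat[i, j] = d[j]

    # splits: remove each internal edge, collect leaf bipartition
    splits = set()
    for idx, (u, v, _) in enumerate(edges):
        remaining = edges[:idx] + edges[idx + 1:]
        adj2 = {}
        for a, b, length in remaining:
            adj2.setdefault(a, []).append(b)
            adj2.setdefault(b, []).append(a)
        seen = {u}
        stack = [u]
        while stack:
            node = stack.pop()
            for nb in adj2.get(node, []):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(labels[i] for i in seen if i < n_taxa)
        other = frozenset(labels) - side
        if 1 < len(side) < n_taxa - 1:
            splits.add(min(side, other, key=lambda s: sorted(s)))
    return labels, mat, splits


def tree_path_lengths(tree):
    """Leaf-to-leaf path lengths computed from the tree structure."""
    adj = {}

    def walk(node):
        for child, length in node.children:
            adj.setdefault(id(node), []).append((id(child), length, None))
            adj.setdefault(id(child), []).append((id(node), length, None))
            walk(child)

    walk(tree.root)
    leaves = {}

    def collect(node):
        if node.label is not None:
            leaves[node.label] = id(node)
        for child, _ in node.children:
            collect(child)

    collect(tree.root)
    out = {}
    for label, start in leaves.items():
        dist = {start: 0.0}
        stack = [start]
        while stack:
            nid = stack.pop()
            for nb, length, _ in adj.get(nid, []):
                if nb not in dist:
                    dist[nb] = dist[nid] + length
                    stack.append(nb)
        for other, oid in leaves.items():
            out[(label, other)] = dist[oid]
    return out


class TestNjTree:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
        )
        tree = nj_tree(dm)
        paths = tree_path_lengths(tree)
        assert paths[("a", "b")] == pytest.approx(3.0)
        assert paths[("a", "c")] == pytest.approx(4.0)
        assert paths[("b", "c")] == pytest.approx(5.0)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_additive_recovery(self, n_taxa, seed):
        labels, mat, true_splits = random_additive_matrix(n_taxa, seed)
        tree = nj_tree(DistanceMatrix(labels, mat))
        assert tree.splits() == true_splits
        paths = tree_path_lengths(tree)
        for i, j in itertools.combinations(range(n_taxa), 2):
            assert paths[(labels[i], labels[j])] == pytest.approx(
                mat[i, j], abs=1e-9
            )

    def test_four_taxon_topology_vs_enumeration(self):
        # four-point oracle: the true split pairs the two closest sums
        labels, mat, true_splits = random_additive_matrix(4, 42)
        sums = {
            frozenset({0, 1}): mat[0, 1] + mat[2, 3],
            frozenset({0, 2}): mat[0, 2] + mat[1, 3],
            frozenset({0, 3}): mat[0, 3] + mat[1, 2],
        }
        best = min(sums, key=sums.get)
        side = frozenset(labels[i] for i in best)
        other = frozenset(labels) - side
        want = min(side, other, key=lambda s: sorted(s))
        tree = nj_tree(DistanceMatrix(labels, mat))
        assert tree.splits() == {want} == true_splits

    def test_degenerate_equal_distances_deterministic(self):
        mat = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("abcd"), mat)
        assert nj_tree(dm).newick() == nj_tree(dm).newick()

    def test_negative_lengths_clamped(self):
        mat = np.array([
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.2, 0.9],
            [0.9, 0.2, 0.0, 0.1],
            [0.9, 0.9, 0.1, 0.0],
        ])
        with pytest.warns(UserWarning, match="clamped"):
            tree = nj_tree(DistanceMatrix(list("abcd"), mat))
        assert ":-" not in tree.newick()

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_newick_parses_with_dendropy(self):
        import dendropy

        labels, mat, _ = random_additive_matrix(6, 3)
        tree = nj_tree(DistanceMatrix(labels, mat))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(labels)


class TestBootstrap:
    def test_well_separated_clades(self):
        clade1 = ["WWWWWWWWWWKKKKKKKKKK", "WWWWWWWWWWKKKKKKKKKD",
                  "WWWWWWWWWWKKKKKKKKKE"]
        clade2 = ["DDDDDDDDDDEEEEEEEEEE", "DDDDDDDDDDEEEEEEEEEK",
                  "DDDDDDDDDDEEEEEEEEEW"]
        aligned = [(f"a{i}", s) for i, s in enumerate(clade1)]
        aligned += [(f"b{i}", s) for i, s in enumerate(clade2)]
        support = bootstrap_support(aligned, n_replicates=100, seed=4)
        clade_split = frozenset({"a0", "a1", "a2"})
        assert clade_split in support
        assert support[clade_split] >= 0.95

    def test_constant_columns_full_support(self):
        aligned = [("a", "WWWW"), ("b", "KKKK"), ("c", "DDDD"), ("d", "EEEE")]
        support = bootstrap_support(aligned, n_replicates=10, seed=0)
        assert all(v == 1.0 for v in support.values())

    def test_seed_determinism(self):
        aligned = [
            ("a", "WWKKDDEE"), ("b", "WWKKDDEK"),
            ("c", "DDEEWWKK"), ("d", "DDEEWWKW"),
        ]
        s1 = bootstrap_support(aligned, n_replicates=25, seed=7)
        s2 = bootstrap_support(aligned, n_replicates=25, seed=7)
        assert s1 == s2

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="equal length"):
            bootstrap_support([("a", "WW"), ("b", "W")], 5, 0)


class TestClassifyFamilies:
    def test_one_shared_family(self):
        members = [
            ("a1", "sp1", ("k",)), ("a2", "sp1", ("k",)),
            ("b1", "sp2", ("k",)),
        ]
        identity = {
            frozenset(p): 0.9
            for p in itertools.combinations(["a1", "a2", "b1"], 2)
        }
        out = classify_families(members, identity)
        assert {fa.family for fa in out} == {"F1"}
        assert all(fa.shared for fa in out)

    def test_two_specific_families(self):
        members = [("a1", "sp1", ("k1",)), ("b1", "sp2", ("k2",))]
        out = classify_families(members, {})
        assert {fa.family for fa in out} == {"F1", "F2"}
        assert not any(fa.shared for fa in out)

    def test_same_skeleton_low_identity_splits(self):
        members = [("a1", "sp1", ("k",)), ("b1", "sp2", ("k",))]
        out = classify_families(members, {frozenset(("a1", "b1")): 0.2})
        assert len({fa.family for fa in out}) == 2

    def test_input_order_invariance(self):
        members = [
            ("a1", "sp1", ("k",)), ("a2", "sp1", ("k",)),
            ("b1", "sp2", ("k2",)),
        ]
        identity = {frozenset(("a1", "a2")): 0.8}
        fwd = classify_families(members, identity)
        rev = classify_families(members[::-1], identity)
        assert fwd == rev

    def test_partition_refines_skeletons(self):
        members = [
            (f"p{i}", "sp1", ("k1",) if i < 3 else ("k2",)) for i in range(6)
        ]
        identity = {
            frozenset((f"p{i}", f"p{j}")): 0.9
            for i in range(6) for j in range(i + 1, 6)
        }
        out = classify_families(members, identity)
        fam_of = {fa.peptide_id: fa.family for fa in out}
        skel_of = {fa.peptide_id: fa.skeleton_key for fa in out}
        for a, b in itertools.combinations(fam_of, 2):
            if fam_of[a] == fam_of[b]:
                assert skel_of[a] == skel_of[b]


class TestCrossSpeciesReport:
    def _assignments(self, spec):
        out = []
        for i, (family, species_list) in enumerate(spec):
            for j, sp in enumerate(species_list):
                out.append(FamilyAssignment(
                    peptide_id=f"{family}_{j}",
                    species=sp,
                    skeleton_key=(f"sk{i}",),
                    family=family,
                    shared=len(set(species_list)) > 1,
                ))
        return out

    def test_shared_and_specific_skeletons(self):
        spec = (
            [(f"F{i}", ["sp1", "sp2"]) for i in range(1, 6)]
            + [(f"F{i}", ["sp2"]) for i in range(6, 8)]
        )
        report = cross_species_report(self._assignments(spec))
        assert report["skeletons"]["total"] == 7
        assert report["skeletons"]["shared"] == 5
        assert report["skeletons"]["specific"] == {"sp2": 2}

    def test_single_species_all_specific(self):
        spec = [("F1", ["sp1"]), ("F2", ["sp1"])]
        report = cross_species_report(self._assignments(spec))
        assert report["skeletons"]["shared"] == 0
        assert report["skeletons"]["specific"] == {"sp1": 2}

    def test_empty(self):
        report = cross_species_report([])
        assert report["families"] == []
        assert report["skeletons"]["total"] == 0

    def test_family_rows(self):
        spec = [("F1", ["sp1", "sp2", "sp1"]), ("F2", ["sp2"])]
        report = cross_species_report(self._assignments(spec))
        rows = {r["family"]: r for r in report["families"]}
        assert rows["F1"]["size"] == 3
        assert rows["F1"]["per_species"] == {"sp1": 2, "sp2": 1}
        assert rows["F1"]["shared"] is True
        assert rows["F2"]["shared"] is False
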