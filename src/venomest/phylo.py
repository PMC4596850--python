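"""Pairwise alignment distances, neighbor-joining trees with bootstrap, and
skeleton + identity family classification across species.

The tree-building route is deliberately simple: end-to-end dynamic-programming
alignment with a linear gap penalty gives percent identity, distances are
d = 1 - identity, and trees come from the Saitou–Nei neighbor-joining
agglomeration with deterministic lexicographic tie-breaking, so the whole
pipeline is reproducible bit-for-bit.
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "PhyloTree",
    "FamilyAssignment",
    "global_align",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "classify_families",
    "cross_species_report",
]


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float       # matches / alignment columns

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Alignment:
    """Optimal global alignment under a linear gap penalty.

    Traceback is deterministic with preference diagonal > up (gap in b) >
    left (gap in a).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    score = np.empty((n + 1, m + 1))
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        row_prev = score[i - 1]
        row = score[i]
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            diag = row_prev[j - 1] + (match if ai == seq_b[j - 1] else mismatch)
            up = row_prev[j] + gap
            left = row[j - 1] + gap
            row[j] = diag if diag >= up and diag >= left else (
                up if up >= left else left
            )
    # traceback
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1, j - 1] + (
                match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            )
            if score[i, j] == diag:
                out_a.append(seq_a[i - 1])
                out_b.append(seq_b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(seq_b[j - 1])
        j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(a == b for a, b in zip(aligned_a, aligned_b))
    return Alignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score[n, m]),
        identity=matches / len(aligned_a),
    )


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


def distance_matrix(sequences: Sequence[tuple], **align_kwargs) -> DistanceMatrix:
    """All-pairs d = 1 - identity from global alignments.

    ``sequences`` is a list of ``(id, sequence)``; duplicate ids are an error.
    """
    labels = [sid for sid, _ in sequences]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate ids: {dupes}")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(sequences[i][1], sequences[j][1], **align_kwargs)
            values[i, j] = values[j, i] = 1.0 - aln.identity
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    label: Optional[str]                  # leaf label, None for internal
    children: list = field(default_factory=list)  # (child, branch length)
    sort_key: str = ""                    # min leaf label in the clade

    def leaves(self) -> frozenset:
        if self.label is not None:
            return frozenset([self.label])
        out = set()
        for child, _ in self.children:
            out |= child.leaves()
        return frozenset(out)


@dataclass
class PhyloTree:
    root: _Node
    labels: list

    def newick(self) -> str:
        def render(node: _Node, length: Optional[float]) -> str:
            if node.label is not None:
                core = node.label
            else:
                inner = ",".join(
                    render(c, l)
                    for c, l in sorted(
                        node.children, key=lambda cl: cl[0].sort_key
                    )
                )
                core = f"({inner})"
            return core if length is None else f"{core}:{length:.6g}"

        return render(self.root, None) + ";"

    def splits(self) -> set:
        """Non-trivial bipartitions, each as the lexicographically smaller
        frozenset side."""
        full = frozenset(self.labels)
        out = set()

        def walk(node: _Node):
            for child, _ in node.children:
                clade = child.leaves()
                if 1 < len(clade) < len(full) - 1:
                    other = full - clade
                    out.add(min(clade, other, key=lambda s: sorted(s)))
                walk(child)

        walk(self.root)
        return out


def _clamped(length: float) -> float:
    if length < 0:
        warnings.warn(
            f"negative branch length {length:.4g} clamped to 0", stacklevel=3
        )
        return 0.0
    return length


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with lexicographic tie-breaking.

    At each step the pair (i, j) minimizing
    ``Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)``
    is joined; among equal-Q pairs the smallest sorted label pair wins, so
    the output tree is deterministic.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    nodes = {
        lbl: _Node(label=lbl, sort_key=lbl) for lbl in matrix.labels
    }
    active = sorted(matrix.labels)
    dist = {
        (a, b): matrix.get(a, b)
        for a, b in itertools.combinations(sorted(matrix.labels), 2)
    }

    def d(a: str, b: str) -> float:
        if a == b:
            return 0.0
        return dist[(a, b) if a < b else (b, a)]

    counter = 0
    while len(active) > 3:
        n_act = len(active)
        row_sums = {a: sum(d(a, b) for b in active) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (n_act - 2) * d(a, b) - row_sums[a] - row_sums[b]
            key = (q, min(nodes[a].sort_key, nodes[b].sort_key),
                   max(nodes[a].sort_key, nodes[b].sort_key))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        dab = d(a, b)
        la = 0.5 * dab + (row_sums[a] - row_sums[b]) / (2 * (n_act - 2))
        lb = dab - la
        new_key = f"_U{counter}"
        counter += 1
        parent = _Node(
            label=None,
            children=[(nodes[a], _clamped(la)), (nodes[b], _clamped(lb))],
            sort_key=min(nodes[a].sort_key, nodes[b].sort_key),
        )
        for c in active:
            if c in (a, b):
                continue
            dnew = 0.5 * (d(a, c) + d(b, c) - dab)
            pair = (new_key, c) if new_key < c else (c, new_key)
            dist[pair] = dnew
        nodes[new_key] = parent
        active = sorted(x for x in active if x not in (a, b)) + [new_key]
        active.sort()
    # final three-way join
    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = _Node(
        label=None,
        children=[
            (nodes[a], _clamped(la)),
            (nodes[b], _clamped(lb)),
            (nodes[c], _clamped(lc)),
        ],
        sort_key=min(nodes[x].sort_key for x in active),
    )
    return PhyloTree(root=root, labels=list(matrix.labels))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _p_distance_matrix(aligned: list) -> DistanceMatrix:
    labels = [lbl for lbl, _ in aligned]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = aligned[i][1], aligned[j][1]
            comparable = diffs = 0
            for ca, cb in zip(sa, sb):
                if ca == "-" or cb == "-":
                    continue
                comparable += 1
                if ca != cb:
                    diffs += 1
            values[i, j] = values[j, i] = (
                diffs / comparable if comparable else 1.0
            )
    return DistanceMatrix(labels, values)


def bootstrap_support(
    aligned: list, n_replicates: int = 100, seed: int = 0
) -> dict:
    """Split support by column resampling of a multiple alignment.

    ``aligned`` is a list of ``(label, aligned_sequence)`` with equal
    lengths. Returns each non-trivial split of the original NJ tree mapped
    to the fraction of replicate trees containing it.
    """
    lengths = {len(s) for _, s in aligned}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    n_cols = lengths.pop()
    if n_cols < 2:
        raise ValueError("alignment needs >= 2 columns")
    original = nj_tree(_p_distance_matrix(aligned))
    target_splits = original.splits()
    counts = {split: 0 for split in target_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = [
            (lbl, "".join(s[c] for c in cols)) for lbl, s in aligned
        ]
        rep_splits = nj_tree(_p_distance_matrix(resampled)).splits()
        for split in target_splits:
            if split in rep_splits:
                counts[split] += 1
    return {split: counts[split] / n_replicates for split in target_splits}


# ---------------------------------------------------------------------------
# family classification
# ---------------------------------------------------------------------------

@dataclass
class FamilyAssignment:
    peptide_id: str
    species: str
    skeleton_key: tuple
    family: str
    shared: bool


def classify_families(
    members: list,
    identity: dict,
    identity_threshold: float = 0.4,
) -> list:
    """Partition peptides into families by skeleton, then identity linkage.

    ``members`` is a list of ``(peptide_id, species, skeleton_key)``;
    ``identity`` maps unordered id pairs (as ``frozenset``) to fractional
    identity. Within each skeleton group, connected components of the
    >= threshold identity graph become families, labeled ``F1``, ``F2``, ...
    by descending size then smallest member id. Output is sorted by
    peptide id and invariant to input order.
    """
    members = sorted(members)
    by_skeleton: dict = defaultdict(list)
    for pid, species, skel in members:
        by_skeleton[skel].append((pid, species))

    components = []
    for skel in sorted(by_skeleton, key=repr):
        group = by_skeleton[skel]
        ids = [pid for pid, _ in group]
        pos = {pid: i for i, pid in enumerate(ids)}
        uf = _UnionFindLabels(len(ids))
        for a, b in itertools.combinations(ids, 2):
            if identity.get(frozenset((a, b)), 0.0) >= identity_threshold:
                uf.union(pos[a], pos[b])
        comp: dict = defaultdict(list)
        for pid, species in group:
            comp[uf.find(pos[pid])].append((pid, species))
        components.extend([(skel, sorted(v)) for v in comp.values()])

    components.sort(key=lambda c: (-len(c[1]), c[1][0][0]))
    out = []
    for rank, (skel, component) in enumerate(components, start=1):
        species_present = {sp for _, sp in component}
        shared = len(species_present) > 1
        for pid, sp in component:
            out.append(
                FamilyAssignment(
                    peptide_id=pid,
                    species=sp,
                    skeleton_key=skel,
                    family=f"F{rank}",
                    shared=shared,
                )
            )
    out.sort(key=lambda fa: fa.peptide_id)
    return out


class _UnionFindLabels:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def cross_species_report(assignments: list) -> dict:
    """Summary of families and skeletons: per-species sizes and sharing."""
    if not assignments:
        return {
            "families": [],
            "skeletons": {"total": 0, "shared": 0, "specific": {}},
            "totals": {},
        }
    families: dict = defaultdict(list)
    for fa in assignments:
        families[fa.family].append(fa)
    family_rows = []
    for family in sorted(families, key=lambda f: int(f[1:])):
        rows = families[family]
        per_species: dict = defaultdict(int)
        for fa in rows:
            per_species[fa.species] += 1
        family_rows.append(
            {
                "family": family,
                "size": len(rows),
                "per_species": dict(sorted(per_species.items())),
                "shared": len(per_species) > 1,
            }
        )
    skeleton_species: dict = defaultdict(set)
    for fa in assignments:
        skeleton_species[fa.skeleton_key].add(fa.species)
    shared = sum(1 for sps in skeleton_species.values() if len(sps) > 1)
    specific: dict = defaultdict(int)
    for sps in skeleton_species.values():
        if len(sps) == 1:
            specific[next(iter(sps))] += 1
    totals: dict = defaultdict(int)
    for fa in assignments:
        totals[fa.species] += 1
    return {
        "families": family_rows,
        "skeletons": {
            "total": len(skeleton_species),
            "shared": shared,
            "specific": dict(sorted(specific.items())),
        },
        "totals": dict(sorted(totals.items())),
    }
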