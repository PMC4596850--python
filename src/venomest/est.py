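"""EST reading, cleaning, identity clustering, and composition statistics."""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ESTRecord",
    "Cluster",
    "CompositionSummary",
    "read_fasta",
    "trim_polya",
    "filter_length",
    "filter_ambiguity",
    "cluster_ests",
    "cluster_size_histogram",
    "composition_summary",
    "HISTOGRAM_BINS",
]

_NT_ALPHABET = frozenset("ACGTN")

HISTOGRAM_BINS = ("1", "2-9", "10-19", "20-70")


@dataclass(frozen=True)
class ESTRecord:
    id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - _NT_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: non-nucleotide characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Cluster:
    id: str
    member_ids: list
    representative: str   # id of the longest member
    size: int

    @property
    def is_singleton(self) -> bool:
        return self.size == 1


@dataclass
class CompositionSummary:
    counts: dict          # category -> count
    fractions: dict       # category -> raw fraction
    percentages: dict     # category -> integer percent (sums to 100)
    total: int


def read_fasta(path) -> list:
    return [
        ESTRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def trim_polya(record: ESTRecord, min_tail: int = 6) -> ESTRecord:
    """Remove a trailing polyA run of at least ``min_tail`` bases."""
    if min_tail < 1:
        raise ValueError("min_tail must be >= 1")
    seq = record.sequence
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    if n - i >= min_tail:
        return ESTRecord(record.id, seq[:i])
    return record


def filter_length(
    records: Iterable[ESTRecord], min_len: int = 400
) -> tuple[list, list]:
    """Keep reads strictly longer than ``min_len``; returns (kept, discarded)."""
    kept, discarded = [], []
    for rec in records:
        (kept if rec.length > min_len else discarded).append(rec)
    return kept, discarded


def filter_ambiguity(
    records: Iterable[ESTRecord], max_n_fraction: float = 0.05
) -> tuple[list, list]:
    """Quality stand-in: drop reads with more than 5% ambiguous bases."""
    kept, discarded = [], []
    for rec in records:
        frac = rec.sequence.count("N") / rec.length if rec.length else 1.0
        (kept if frac <= max_n_fraction else discarded).append(rec)
    return kept, discarded


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _identity_at_offset(a: str, b: str, offset: int) -> tuple[int, int]:
    """(matches, overlap) of the ungapped alignment a[i] vs b[i - offset]."""
    start_a = max(0, offset)
    end_a = min(len(a), len(b) + offset)
    overlap = end_a - start_a
    if overlap <= 0:
        return 0, 0
    matches = 0
    for i in range(start_a, end_a):
        ca, cb = a[i], b[i - offset]
        if ca == cb and ca != "N":   # N never counts as a match
            matches += 1
    return matches, overlap


def _pair_linked(
    a: str, b_variants: tuple, votes_by_strand: dict,
    identity_threshold: float, min_overlap: int,
) -> bool:
    for strand, votes in votes_by_strand.items():
        query = b_variants[0] if strand == "+" else b_variants[1]
        for offset, _ in votes.most_common(3):
            matches, overlap = _identity_at_offset(a, query, offset)
            if overlap >= min_overlap and matches / overlap >= identity_threshold:
                return True
    return False


def _is_low_complexity(kmer: str) -> bool:
    return len(set(kmer)) <= 2


class _UnionFind:
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


def cluster_ests(
    records: list,
    identity_threshold: float = 0.95,
    min_overlap: int = 100,
    k: int = 12,
) -> list:
    """Single-linkage identity clustering of EST reads.

    Two reads are linked when their best ungapped overlap (either strand,
    seeded by shared k-mers) reaches ``identity_threshold`` over at least
    ``min_overlap`` bases. Output is deterministic: clusters sorted by
    descending size, then by representative id; members sorted by id.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must lie in (0, 1]")
    # records are handled in id order so the result is input-order invariant
    records = sorted(records, key=lambda r: r.id)
    fwd = [r.sequence for r in records]
    rc = [str(Seq(s).reverse_complement()) for s in fwd]

    index: dict = defaultdict(list)  # kmer -> [(record idx, pos), ...]
    for idx, seq in enumerate(fwd):
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos:pos + k]
            if "N" not in kmer and not _is_low_complexity(kmer):
                index[kmer].append((idx, pos))

    # shared-kmer diagonal votes per candidate pair, both orientations
    votes: dict = defaultdict(Counter)  # (i, j, strand) -> offset votes
    for j in range(len(records)):
        for strand, seq in (("+", fwd[j]), ("-", rc[j])):
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" in kmer or _is_low_complexity(kmer):
                    continue
                for i, qpos in index.get(kmer, ()):
                    if i < j:
                        votes[(i, j, strand)][qpos - pos] += 1

    by_pair: dict = defaultdict(dict)
    for (i, j, strand), counter in votes.items():
        by_pair[(i, j)][strand] = counter

    uf = _UnionFind(len(records))
    for (i, j), votes_by_strand in by_pair.items():
        if uf.find(i) == uf.find(j):
            continue
        if _pair_linked(
            fwd[i], (fwd[j], rc[j]), votes_by_strand,
            identity_threshold, min_overlap,
        ):
            uf.union(i, j)
    groups: dict = defaultdict(list)
    for i in range(len(records)):
        groups[uf.find(i)].append(i)
    clusters = []
    for members in groups.values():
        recs = sorted(
            (records[i] for i in members),
            key=lambda r: (-r.length, r.id),
        )
        clusters.append(
            Cluster(
                id="",
                member_ids=sorted(r.id for r in recs),
                representative=recs[0].id,
                size=len(recs),
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.representative))
    for i, c in enumerate(clusters, start=1):
        c.id = f"CL{i:04d}"
    return clusters


def cluster_size_histogram(clusters: Iterable[Cluster]) -> dict:
    """Counts of clusters per size bin {1, 2-9, 10-19, 20-70+}."""
    hist = {b: 0 for b in HISTOGRAM_BINS}
    for c in clusters:
        if c.size < 1:
            raise ValueError(f"cluster {c.id} has size {c.size}")
        if c.size == 1:
            hist["1"] += 1
        elif c.size <= 9:
            hist["2-9"] += 1
        elif c.size <= 19:
            hist["10-19"] += 1
        else:
            hist["20-70"] += 1
    return hist


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

_CATEGORIES = ("toxin", "cellular", "unknown")


def composition_summary(annotations: dict) -> CompositionSummary:
    """Per-category counts, raw fractions, and integer percentages.

    ``annotations`` maps EST id -> category. Percentages use
    largest-remainder rounding so they sum to exactly 100.
    """
    bad = sorted(
        est_id for est_id, cat in annotations.items() if cat not in _CATEGORIES
    )
    if bad:
        raise ValueError(f"unlabeled or mislabeled ids: {bad}")
    counts = {cat: 0 for cat in _CATEGORIES}
    for cat in annotations.values():
        counts[cat] += 1
    total = sum(counts.values())
    if total == 0:
        return CompositionSummary({}, {}, {}, 0)
    fractions = {cat: counts[cat] / total for cat in _CATEGORIES}
    floors = {cat: int(fractions[cat] * 100) for cat in _CATEGORIES}
    shortfall = 100 - sum(floors.values())
    remainders = sorted(
        _CATEGORIES,
        key=lambda cat: (fractions[cat] * 100 - floors[cat], counts[cat]),
        reverse=True,
    )
    percentages = dict(floors)
    for cat in remainders[:shortfall]:
        percentages[cat] += 1
    return CompositionSummary(counts, fractions, percentages, total)
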