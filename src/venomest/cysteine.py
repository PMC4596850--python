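"""Cysteine-pattern extraction, notation parsing, and scaffold canonicalization.

Disulfide-rich venom peptides are conventionally described by the spacing of
their cysteines, written with ``C`` / ``x_n`` tokens (e.g. ``-Cx6-CxC-CC-``).
This module extracts such patterns from mature peptide sequences, parses and
re-prints the notation, collapses patterns to spacer-free *skeletons*
(``CC`` adjacency, ``CXC`` single spacing, ``-`` for anything longer), and
evaluates the two structural motifs used to flag putative ion-channel
blockers:

* **PSM** — exactly six residues between cysteines 1 and 2, and no residue
  between cysteines 3 and 4.
* **ESM** — at least a pair of ``CXC`` fragments in the C-terminal half of
  the cysteine framework.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, Union

__all__ = [
    "VARIABLE",
    "GapSpec",
    "GapClass",
    "CysteinePattern",
    "Skeleton",
    "MaturePeptideProfile",
    "AcyclicPeptideError",
    "PatternSyntaxError",
    "MixedGapClassError",
    "extract_pattern",
    "parse_pattern_string",
    "render_pattern",
    "skeletonize",
    "detect_psm",
    "detect_esm",
    "count_distinct_skeletons",
    "profile_mature",
]

#: Sentinel for a gap of unspecified length ("x_n" or a bare hyphen).
VARIABLE = "n"

#: A gap descriptor: an exact length, a set of candidate lengths
#: (``x_4/8``), or :data:`VARIABLE`.
GapSpec = Union[int, frozenset, str]


class AcyclicPeptideError(ValueError):
    """Raised for sequences with fewer than two cysteines."""


class PatternSyntaxError(ValueError):
    """Raised when a pattern string cannot be tokenized; carries the offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


class MixedGapClassError(ValueError):
    """Raised when a gap set spans incompatible skeleton classes."""


class GapClass(str, Enum):
    ADJACENT = "adjacent"  # 0 residues between cysteines -> "CC"
    SINGLE = "single"      # exactly 1 residue -> "CXC"
    VARIABLE = "variable"  # >= 2 residues, or unspecified -> "-"


@dataclass(frozen=True)
class CysteinePattern:
    """Ordered inter-cysteine gaps of a mature peptide or notation string."""

    n_cys: int
    gaps: tuple
    leading: GapSpec = 0
    trailing: GapSpec = 0

    def __post_init__(self):
        if self.n_cys < 2:
            raise AcyclicPeptideError(
                f"pattern needs >= 2 cysteines, got {self.n_cys}"
            )
        if len(self.gaps) != self.n_cys - 1:
            raise ValueError(
                f"{self.n_cys} cysteines require {self.n_cys - 1} gaps, "
                f"got {len(self.gaps)}"
            )
        for g in self.gaps:
            if isinstance(g, int) and g < 0:
                raise ValueError(f"negative gap {g}")

    @property
    def max_disulfides(self) -> int:
        return self.n_cys // 2

    def first_gap(self) -> GapSpec:
        return self.gaps[0]


@dataclass(frozen=True)
class Skeleton:
    """Spacer-free canonical form of a cysteine pattern."""

    n_cys: int
    gap_classes: tuple

    def __post_init__(self):
        if len(self.gap_classes) != self.n_cys - 1:
            raise ValueError("gap class count must be n_cys - 1")

    @property
    def rendering(self) -> str:
        """Discussion-style string: CC for adjacent, CXC for single, '-' else."""
        parts = ["C"]
        for cls in self.gap_classes:
            if cls is GapClass.ADJACENT:
                parts.append("C")
            elif cls is GapClass.SINGLE:
                parts.append("XC")
            else:
                parts.append("-C")
        return "".join(parts)

    def key(self) -> tuple:
        """Equality key for skeleton grouping: classes plus cysteine count."""
        return (self.n_cys, tuple(c.value for c in self.gap_classes))


@dataclass
class MaturePeptideProfile:
    """Physicochemical / structural summary of one mature peptide."""

    id: str
    length: int
    n_cys: int
    max_disulfides: int
    psm: bool
    esm: bool
    pattern: CysteinePattern | None
    skeleton: Skeleton | None
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# extraction from sequence
# ---------------------------------------------------------------------------

def extract_pattern(mature_aa: str) -> CysteinePattern:
    """Read the exact cysteine spacing off a mature peptide sequence.

    Raises :class:`AcyclicPeptideError` if the sequence carries fewer than
    two cysteines (such peptides are excluded from scaffold grouping).
    """
    positions = [i for i, ch in enumerate(mature_aa) if ch == "C"]
    if len(positions) < 2:
        raise AcyclicPeptideError(
            f"sequence has {len(positions)} cysteine(s); pattern undefined"
        )
    gaps = tuple(
        positions[k + 1] - positions[k] - 1 for k in range(len(positions) - 1)
    )
    return CysteinePattern(
        n_cys=len(positions),
        gaps=gaps,
        leading=positions[0],
        trailing=len(mature_aa) - positions[-1] - 1,
    )


# ---------------------------------------------------------------------------
# notation parser / printer
# ---------------------------------------------------------------------------

_DASHES = "‐‑‒–—―−"


def _normalize(notation: str) -> str:
    out = []
    for ch in notation:
        if ch.isspace() or ch == "_":
            continue
        if ch in _DASHES:
            out.append("-")
        else:
            out.append(ch)
    return "".join(out)


def _tokenize(text: str):
    """Yield ('C',), ('dash',), ('gap', value) tokens."""
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "C":
            yield ("C", None, i)
            i += 1
        elif ch == "-":
            yield ("dash", None, i)
            i += 1
        elif ch in "xX":
            j = i + 1
            if j < n and text[j] == "n":
                yield ("gap", VARIABLE, i)
                i = j + 1
            elif j < n and text[j].isdigit():
                k = j
                while k < n and text[k].isdigit():
                    k += 1
                first = int(text[j:k])
                if k < n and text[k] == "/":
                    k += 1
                    m = k
                    while m < n and text[m].isdigit():
                        m += 1
                    if m == k:
                        raise PatternSyntaxError("expected digits after '/'", k)
                    yield ("gap", frozenset({first, int(text[k:m])}), i)
                    i = m
                else:
                    yield ("gap", first, i)
                    i = k
            else:
                # bare "x" denotes a single-residue spacer
                yield ("gap", 1, i)
                i = j
        else:
            raise PatternSyntaxError(f"unexpected character {ch!r}", i)


def _combine(contribs: list, dash_seen: bool, where: str) -> GapSpec:
    """Resolve the tokens collected between two consecutive C's into a gap."""
    if not contribs:
        return VARIABLE if dash_seen else 0
    if any(c == VARIABLE for c in contribs):
        return VARIABLE
    sets = [c for c in contribs if isinstance(c, frozenset)]
    exact = sum(c for c in contribs if isinstance(c, int))
    if len(sets) > 1:
        raise PatternSyntaxError(f"multiple gap sets in one {where} gap", 0)
    if sets:
        return frozenset(v + exact for v in sets[0])
    return exact


def parse_pattern_string(notation: str) -> CysteinePattern:
    """Parse ``C``/``x_n`` cysteine-pattern notation into a pattern.

    Accepted dialects: underscored subscripts (``x_6_``), bare ``x`` for a
    single spacer, ``x_a/b`` alternatives, ``x_n`` for unspecified length,
    unicode dashes, and skeleton-style strings such as ``C-C-CC-CXC-CXC``.
    A hyphen directly joining two cysteines denotes a variable gap; a hyphen
    adjacent to an explicit spacer is a separator only.
    """
    text = _normalize(notation)
    n_cys = 0
    gaps: list = []
    contribs: list = []
    dash_seen = False
    saw_c = False
    leading: GapSpec = 0
    for kind, value, _ in _tokenize(text):
        if kind == "C":
            if not saw_c:
                leading = _combine(contribs, dash_seen, "leading")
                saw_c = True
            else:
                gaps.append(_combine(contribs, dash_seen, "internal"))
            n_cys += 1
            contribs, dash_seen = [], False
        elif kind == "dash":
            dash_seen = True
        else:
            contribs.append(value)
    if n_cys < 2:
        raise AcyclicPeptideError(f"notation contains {n_cys} cysteine(s)")
    trailing = _combine(contribs, dash_seen, "trailing")
    return CysteinePattern(
        n_cys=n_cys, gaps=tuple(gaps), leading=leading, trailing=trailing
    )


def _gap_token(gap: GapSpec) -> str:
    if gap == VARIABLE:
        return "-"
    if isinstance(gap, frozenset):
        lo, hi = sorted(gap)
        return f"x{lo}/{hi}-"
    if gap == 0:
        return ""
    if gap == 1:
        return "x"
    return f"x{gap}-"


def render_pattern(pattern: CysteinePattern) -> str:
    """Print a pattern in canonical notation; inverse of the parser."""
    parts = []
    if pattern.leading == VARIABLE:
        parts.append("-")
    elif isinstance(pattern.leading, int) and pattern.leading > 0:
        parts.append(f"x{pattern.leading}-")
    parts.append("C")
    for gap in pattern.gaps:
        parts.append(_gap_token(gap))
        parts.append("C")
    if pattern.trailing == VARIABLE:
        parts.append("-")
    elif isinstance(pattern.trailing, int) and pattern.trailing > 0:
        parts.append(f"-x{pattern.trailing}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# skeletons
# ---------------------------------------------------------------------------

def _classify_gap(gap: GapSpec) -> GapClass:
    if gap == VARIABLE:
        return GapClass.VARIABLE
    if isinstance(gap, frozenset):
        classes = {_classify_gap(v) for v in gap}
        if len(classes) > 1:
            raise MixedGapClassError(
                f"gap alternatives {sorted(gap)} span multiple skeleton classes"
            )
        return classes.pop()
    if gap == 0:
        return GapClass.ADJACENT
    if gap == 1:
        return GapClass.SINGLE
    return GapClass.VARIABLE


def skeletonize(pattern: CysteinePattern) -> Skeleton:
    """Collapse exact spacers to the three-way adjacency classification."""
    return Skeleton(
        n_cys=pattern.n_cys,
        gap_classes=tuple(_classify_gap(g) for g in pattern.gaps),
    )


def count_distinct_skeletons(
    patterns: Iterable[CysteinePattern],
) -> tuple[int, dict]:
    """Group patterns by skeleton; returns (count, key -> list of indices).

    Two patterns share a skeleton only when both the gap-class sequence and
    the cysteine count agree. Group order is first occurrence.
    """
    groups: dict = {}
    for idx, pat in enumerate(patterns):
        key = skeletonize(pat).key()
        groups.setdefault(key, []).append(idx)
    return len(groups), groups


# ---------------------------------------------------------------------------
# structural motifs
# ---------------------------------------------------------------------------

def _gap_matches(gap: GapSpec, target: int) -> bool:
    if isinstance(gap, frozenset):
        return target in gap
    return gap == target


def detect_psm(pattern: CysteinePattern) -> bool:
    """Principal Structural Motif: C1-x6-C2 spacing and C3C4 adjacency."""
    if pattern.n_cys < 4:
        return False
    return _gap_matches(pattern.gaps[0], 6) and _gap_matches(pattern.gaps[2], 0)


def detect_esm(pattern: CysteinePattern, region_fraction: float = 0.5) -> bool:
    """Extra Structural Motif: >= 2 CXC units in the C-terminal region.

    The region covers gaps whose left cysteine index (1-based) exceeds
    ``n_cys * (1 - region_fraction)``; by default the last half of the
    cysteine framework.
    """
    if pattern.n_cys < 4:
        return False
    cutoff = pattern.n_cys * (1.0 - region_fraction)
    n_single = 0
    for i, gap in enumerate(pattern.gaps, start=1):
        if i > cutoff and _classify_gap(gap) is GapClass.SINGLE:
            n_single += 1
    return n_single >= 2


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def profile_mature(peptide_id: str, mature_aa: str) -> MaturePeptideProfile:
    """Build the full structural profile of one mature peptide sequence."""
    n_cys = mature_aa.count("C")
    try:
        pattern = extract_pattern(mature_aa)
    except AcyclicPeptideError:
        return MaturePeptideProfile(
            id=peptide_id,
            length=len(mature_aa),
            n_cys=n_cys,
            max_disulfides=n_cys // 2,
            psm=False,
            esm=False,
            pattern=None,
            skeleton=None,
            flags=["acyclic"],
        )
    return MaturePeptideProfile(
        id=peptide_id,
        length=len(mature_aa),
        n_cys=n_cys,
        max_disulfides=n_cys // 2,
        psm=detect_psm(pattern),
        esm=detect_esm(pattern),
        pattern=pattern,
        skeleton=skeletonize(pattern),
    )
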