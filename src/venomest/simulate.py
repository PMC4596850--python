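"""Synthetic EST libraries with known precursor architecture and redundancy.

The generator emits nucleotide EST reads plus a ground-truth table so every
downstream stage (clustering, precursor parsing, pattern extraction, family
classification) can be tested closed-loop without external data.

Construction guarantees, at substitution_rate = 0:

* the signal-cut heuristic recovers the generated signal length exactly
  (the generated signal is the only admissible cut in the 16-25 window);
* the PQM scanner recovers the generated propeptide boundary exactly
  (no competing arginine site in the scan window);
* amidation detection recovers the appended tail exactly
  (trailing-context residues never mimic a G/GK/GR signal);
* the extracted cysteine pattern skeletonizes back to the template skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from . import cysteine
from .cysteine import GapClass, Skeleton, parse_pattern_string, skeletonize

__all__ = [
    "FamilyTemplate",
    "LibraryConfig",
    "PrecursorTruth",
    "ESTTruth",
    "ConfigurationError",
    "generate_precursor",
    "reverse_translate",
    "generate_library",
    "default_templates",
    "write_fasta",
    "truth_table_rows",
    "TRUTH_COLUMNS",
]

SIGNAL_MIN, SIGNAL_MAX = 16, 25
PRO_MIN, PRO_MAX = 12, 38
PQM_GUARD = 38  # no competing R allowed this deep into the remainder

# residue pools; none of the non-signal pools contain C, and pools that can
# fall inside the 25-aa signal-scan window avoid the cut residues {A,G,S,C,T}
_SIGNAL_HYDROPHOBIC = "LIVFMW"
_SIGNAL_FILLER = "KNQEHYPD"
_SAFE_HYDROPHILIC = "NQEDKHPY"       # window-safe, R-free
_PQM_FILLER = "PQN"
_TRAIL_POOL = "SNQTDEPHYFWVLIA"      # no G/K/R: cannot mimic amidation tails
_NEUTRAL_POOL = "SNQTAFWYPHVLIMG"

_BIN_RANGES = {"1": (1, 1), "2-9": (2, 9), "10-19": (10, 19), "20-70": (20, 70)}


class ConfigurationError(ValueError):
    """Infeasible template or library configuration."""


@dataclass
class FamilyTemplate:
    """Blueprint for one toxin family."""

    name: str
    skeleton_string: str
    spacer_ranges: list           # (lo, hi) per inter-cysteine gap
    mature_length_range: tuple    # genetic mature length incl. amidation tail
    has_propeptide: bool
    amidation_tail: str = ""      # "", "G", "GK" or "GR"
    basicity_bias: float = 0.5
    charged_fraction: float = 0.35

    skeleton: Skeleton = field(init=False)

    def __post_init__(self):
        self.skeleton = skeletonize(parse_pattern_string(self.skeleton_string))
        n_gaps = self.skeleton.n_cys - 1
        if len(self.spacer_ranges) != n_gaps:
            raise ConfigurationError(
                f"template {self.name}: {len(self.spacer_ranges)} spacer "
                f"ranges for {n_gaps} gaps"
            )
        for (lo, hi), cls in zip(self.spacer_ranges, self.skeleton.gap_classes):
            if lo > hi or lo < 0:
                raise ConfigurationError(
                    f"template {self.name}: bad spacer range ({lo}, {hi})"
                )
            want = {
                GapClass.ADJACENT: (0, 0),
                GapClass.SINGLE: (1, 1),
            }.get(cls)
            if want is not None and (lo, hi) != want:
                raise ConfigurationError(
                    f"template {self.name}: spacer range ({lo}, {hi}) "
                    f"incompatible with {cls.value} gap"
                )
            if cls is GapClass.VARIABLE and lo < 2:
                raise ConfigurationError(
                    f"template {self.name}: variable gap needs spacers >= 2"
                )
        lo, hi = self.mature_length_range
        if not (35 <= lo <= hi <= 86):
            raise ConfigurationError(
                f"template {self.name}: mature length range {lo}-{hi} "
                "outside [35, 86]"
            )
        if self.amidation_tail not in ("", "G", "GK", "GR"):
            raise ConfigurationError(
                f"template {self.name}: bad amidation tail "
                f"{self.amidation_tail!r}"
            )
        if not 0.0 <= self.basicity_bias <= 1.0:
            raise ConfigurationError("basicity_bias must lie in [0, 1]")


@dataclass
class PrecursorTruth:
    """A generated precursor with its true region coordinates (1-based)."""

    aa_sequence: str
    family: str
    signal_range: tuple
    propeptide_range: Optional[tuple]
    mature_range: tuple
    amidation_tail: str
    skeleton_rendering: str

    @property
    def mature_genetic(self) -> str:
        a, b = self.mature_range
        return self.aa_sequence[a - 1:b]


@dataclass
class ESTTruth:
    est_id: str
    transcript_id: str
    category: str
    family: str
    signal_range: Optional[tuple]
    propeptide_range: Optional[tuple]
    mature_range: Optional[tuple]
    amidation_tail: str
    skeleton_rendering: str


@dataclass
class LibraryConfig:
    family_sizes: dict            # template name -> transcript count
    category_mix: dict            # {"toxin": n, "cellular": n, "unknown": n}
    redundancy_bins: dict = field(
        default_factory=lambda: {"1": 0.70, "2-9": 0.23,
                                 "10-19": 0.05, "20-70": 0.02}
    )
    substitution_rate: float = 0.0
    polya_length_range: tuple = (8, 30)
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.family_sizes.values()):
            raise ConfigurationError("negative family size")
        if any(v < 0 for v in self.category_mix.values()):
            raise ConfigurationError("negative category count")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ConfigurationError("substitution_rate must lie in [0, 1)")
        if set(self.redundancy_bins) - set(_BIN_RANGES):
            raise ConfigurationError(
                f"unknown redundancy bins {set(self.redundancy_bins) - set(_BIN_RANGES)}"
            )
        total = sum(self.redundancy_bins.values())
        if total <= 0:
            raise ConfigurationError("redundancy bin weights sum to zero")


# ---------------------------------------------------------------------------
# precursor generation
# ---------------------------------------------------------------------------

def _choice(rng, pool: str) -> str:
    return pool[int(rng.integers(len(pool)))]


def _mature_body_residue(rng, template: FamilyTemplate) -> str:
    if rng.random() < template.charged_fraction:
        if rng.random() < template.basicity_bias:
            return _choice(rng, "KR")
        return _choice(rng, "DE")
    return _choice(rng, _NEUTRAL_POOL)


def _attempt_precursor(template: FamilyTemplate, rng) -> PrecursorTruth:
    # signal: M + hydrophobic-biased body + small cut residue; nothing inside
    # positions 2..s-1 belongs to the admissible cut set
    s = int(rng.integers(SIGNAL_MIN, SIGNAL_MAX + 1))
    signal = ["M"]
    for _ in range(s - 2):
        pool = _SIGNAL_HYDROPHOBIC if rng.random() < 0.7 else _SIGNAL_FILLER
        signal.append(_choice(rng, pool))
    signal.append("A")
    signal = "".join(signal)

    if template.has_propeptide:
        pro_len = int(rng.integers(PRO_MIN, PRO_MAX + 1))
        pro = [_choice(rng, _SAFE_HYDROPHILIC) for _ in range(pro_len - 4)]
        pro += ["E", _choice(rng, _PQM_FILLER), _choice(rng, _PQM_FILLER), "R"]
        pro = "".join(pro)
        lead_len = int(rng.integers(0, 5))
    else:
        pro = ""
        # keep every cysteine and every mature residue out of the 25-aa
        # signal-scan window
        lead_len = max(0, SIGNAL_MAX - s)

    spacers = [int(rng.integers(lo, hi + 1)) for lo, hi in template.spacer_ranges]
    tail = template.amidation_tail
    base = lead_len + template.skeleton.n_cys + sum(spacers) + len(tail)
    lo, hi = template.mature_length_range
    if base > hi:
        raise ConfigurationError(
            f"template {template.name}: minimum mature length {base} exceeds "
            f"range maximum {hi}"
        )
    target = int(rng.integers(max(lo, base), hi + 1))
    trail_len = target - base

    lead = "".join(_choice(rng, _SAFE_HYDROPHILIC) for _ in range(lead_len))
    body = [lead]
    for spacer in spacers:
        body.append("C")
        body.append(
            "".join(_mature_body_residue(rng, template) for _ in range(spacer))
        )
    body.append("C")
    body.append("".join(_choice(rng, _TRAIL_POOL) for _ in range(trail_len)))
    mature_body = list("".join(body))

    # PQM guard: no competing cleavage-competent arginine within the scan
    # window of the remainder (propeptide + mature)
    guard = PQM_GUARD - len(pro)
    for i in range(min(guard, len(mature_body))):
        if mature_body[i] == "R":
            mature_body[i] = "K"
    mature = "".join(mature_body) + tail

    aa = signal + pro + mature
    pro_range = (s + 1, s + len(pro)) if pro else None
    mature_start = s + len(pro) + 1
    return PrecursorTruth(
        aa_sequence=aa,
        family=template.name,
        signal_range=(1, s),
        propeptide_range=pro_range,
        mature_range=(mature_start, len(aa)),
        amidation_tail=tail,
        skeleton_rendering=template.skeleton.rendering,
    )


def generate_precursor(
    template: FamilyTemplate, rng, max_tries: int = 50
) -> PrecursorTruth:
    """Draw one precursor realizing the template; retries infeasible draws."""
    last_err = None
    for _ in range(max_tries):
        try:
            truth = _attempt_precursor(template, rng)
        except ConfigurationError as err:
            last_err = err
            continue
        return truth
    raise ConfigurationError(
        f"template {template.name}: no feasible precursor in {max_tries} "
        f"tries ({last_err})"
    )


# ---------------------------------------------------------------------------
# reverse translation
# ---------------------------------------------------------------------------

def _codon_map() -> dict:
    table = CodonTable.unambiguous_dna_by_id[1]
    codons: dict = {}
    for codon, aa in sorted(table.forward_table.items()):
        codons.setdefault(aa, []).append(codon)
    codons["*"] = sorted(table.stop_codons)
    return codons


_CODONS = _codon_map()


def reverse_translate(
    aa_sequence: str, policy: str = "first", rng=None
) -> str:
    """Encode an amino-acid sequence as DNA; a stop codon is appended.

    ``policy="first"`` picks the alphabetically first codon for each residue
    (deterministic); ``policy="random"`` draws uniformly using ``rng``.
    Sequences beginning with M therefore begin with ATG. Translating the
    output with the standard genetic code returns the input.
    """
    if not aa_sequence:
        raise ValueError("empty amino-acid sequence")
    if policy not in ("first", "random"):
        raise ValueError(f"unknown codon policy {policy!r}")
    if policy == "random" and rng is None:
        raise ValueError("random policy requires an rng")
    out = []
    for pos, aa in enumerate(aa_sequence + "*", start=1):
        options = _CODONS.get(aa)
        if options is None:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
        if policy == "first":
            out.append(options[0])
        else:
            out.append(options[int(rng.integers(len(options)))])
    return "".join(out)


# ---------------------------------------------------------------------------
# library assembly
# ---------------------------------------------------------------------------

def _substream(seed: int, *counters: int):
    return np.random.default_rng([seed, *counters])


def _draw_copy_count(rng, bins: dict, remaining: int) -> int:
    names = sorted(bins)
    weights = np.array([bins[n] for n in names], dtype=float)
    weights /= weights.sum()
    bin_name = names[int(rng.choice(len(names), p=weights))]
    lo, hi = _BIN_RANGES[bin_name]
    return min(int(rng.integers(lo, hi + 1)), remaining)


def _mutate(nt: str, rate: float, rng) -> str:
    if rate <= 0:
        return nt
    bases = "ACGT"
    seq = list(nt)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alternatives = bases.replace(seq[i], "") if seq[i] in bases else bases
        seq[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(seq)


def _random_decoy(rng, length: int) -> str:
    return "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=length))


def _three_prime_utr(rng) -> str:
    # A-free so polyA trimming can never reach into the stop codon
    length = int(rng.integers(20, 61))
    return "".join("CGT"[int(b)] for b in rng.integers(0, 3, size=length))


def generate_library(
    config: LibraryConfig, templates: list
) -> tuple[list, list]:
    """Emit (records, truth) for a full synthetic EST library.

    ``records`` is a list of ``(est_id, nucleotide_sequence)`` in a
    deterministic order; ``truth`` is the matching list of :class:`ESTTruth`.
    Redundant copies of a transcript differ only by substitutions and polyA
    length. Identical config + seed yields byte-identical output.
    """
    by_name = {t.name: t for t in templates}
    missing = set(config.family_sizes) - set(by_name)
    if missing:
        raise ConfigurationError(f"no template for families {sorted(missing)}")

    seed = config.seed
    stream = 0
    transcripts = []  # (transcript_id, category, nt, PrecursorTruth | None)
    for name in sorted(config.family_sizes):
        template = by_name[name]
        for i in range(config.family_sizes[name]):
            rng = _substream(seed, 1, stream)
            stream += 1
            truth = generate_precursor(template, rng)
            nt = reverse_translate(truth.aa_sequence, policy="random", rng=rng)
            nt += _three_prime_utr(rng)
            transcripts.append((f"TX_{name}_{i:03d}", "toxin", nt, truth))
    for category, prefix in (("cellular", "CEL"), ("unknown", "UNK")):
        n_transcripts = max(1, config.category_mix.get(category, 0) // 3)
        if config.category_mix.get(category, 0) == 0:
            n_transcripts = 0
        for i in range(n_transcripts):
            rng = _substream(seed, 2, stream)
            stream += 1
            length = int(rng.integers(450, 900))
            transcripts.append(
                (f"{prefix}_{i:03d}", category, _random_decoy(rng, length), None)
            )

    records: list = []
    truths: list = []
    est_counter = 0
    for category in ("toxin", "cellular", "unknown"):
        pool = [t for t in transcripts if t[1] == category]
        remaining = config.category_mix.get(category, 0)
        if remaining and not pool:
            raise ConfigurationError(
                f"category {category!r} requested but no transcripts available"
            )
        idx = 0
        while remaining > 0:
            tid, cat, nt, truth = pool[idx % len(pool)]
            rng = _substream(seed, 3, est_counter)
            copies = _draw_copy_count(rng, config.redundancy_bins, remaining)
            if idx // len(pool) > 0:
                copies = 1  # wrapped around: pad one copy at a time
            for _ in range(copies):
                copy_rng = _substream(seed, 4, est_counter)
                lo, hi = config.polya_length_range
                polya = "A" * int(copy_rng.integers(lo, hi + 1))
                seq = _mutate(nt, config.substitution_rate, copy_rng) + polya
                est_id = f"EST{est_counter:05d}"
                records.append((est_id, seq))
                truths.append(
                    ESTTruth(
                        est_id=est_id,
                        transcript_id=tid,
                        category=cat,
                        family=truth.family if truth else "",
                        signal_range=truth.signal_range if truth else None,
                        propeptide_range=(
                            truth.propeptide_range if truth else None
                        ),
                        mature_range=truth.mature_range if truth else None,
                        amidation_tail=truth.amidation_tail if truth else "",
                        skeleton_rendering=(
                            truth.skeleton_rendering if truth else ""
                        ),
                    )
                )
                est_counter += 1
            remaining -= copies
            idx += 1
    return records, truths


# ---------------------------------------------------------------------------
# defaults and I/O
# ---------------------------------------------------------------------------

def default_templates() -> list:
    """Eight built-in family blueprints spanning the architecture space:
    propeptide-bearing and propeptide-free families, 8-12 cysteines,
    adjacent/single/variable gap mixes, and all three amidation tails."""
    V = (2, 8)
    return [
        FamilyTemplate(
            "A", "-Cx7-Cx8-CCx4-Cx5-CCx3-Cx3-Cx17-C-",
            [(7, 7), (8, 8), (0, 0), (4, 4), (5, 5), (0, 0), (3, 3), (3, 3),
             (17, 17)],
            (60, 80), has_propeptide=False, amidation_tail="G",
        ),
        FamilyTemplate(
            "B", "-Cx6C-CC-CxC-CxC-",
            [(6, 6), V, (0, 0), V, (1, 1), V, (1, 1)],
            (35, 45), has_propeptide=True, basicity_bias=0.7,
        ),
        FamilyTemplate(
            "C", "-Cx6-Cx3-Cx-CCx6-Cx5-Cx7-Cx6-Cx6-C-",
            [(6, 6), (3, 3), (1, 1), (0, 0), (6, 6), (5, 5), (7, 7), (6, 6),
             (6, 6)],
            (53, 62), has_propeptide=True,
        ),
        FamilyTemplate(
            "D", "Cx6-Cx6-CCx4/8-CxC-x6/7-CxC-",
            [(6, 6), (6, 6), (0, 0), (4, 8), (1, 1), (6, 7), (1, 1)],
            (43, 51), has_propeptide=True, amidation_tail="GK",
            basicity_bias=0.8,
        ),
        FamilyTemplate(
            "E", "-Cx6-Cx3-Cx-CC-x5-CxC-x10-CxC-x7-Cx6-Cx7-Cxn-",
            [(6, 6), (3, 3), (1, 1), (0, 0), (5, 5), (1, 1), (10, 10), (1, 1),
             (7, 7), (6, 6), (7, 7)],
            (70, 80), has_propeptide=True,
        ),
        FamilyTemplate(
            "F", "-Cx6-Cx3/4-Cx-CC-x5/6-CxC-x6/7-CxC-x7-Cx6-Cx6/12-Cxn-",
            [(6, 6), (3, 4), (1, 1), (0, 0), (5, 6), (1, 1), (6, 7), (1, 1),
             (7, 7), (6, 6), (6, 12)],
            (66, 78), has_propeptide=True,
        ),
        FamilyTemplate(
            "G", "-Cx5-Cx4-CC-x8-C-x9-C-x12-CxC-x5-C-x5-C-",
            [(5, 5), (4, 4), (0, 0), (8, 8), (9, 9), (12, 12), (1, 1), (5, 5),
             (5, 5)],
            (64, 74), has_propeptide=False,
        ),
        FamilyTemplate(
            "H", "Cx5-Cx4-CC-x10-Cx9-Cx16-CxC-x5-Cx18-Cxn",
            [(5, 5), (4, 4), (0, 0), (10, 10), (9, 9), (16, 16), (1, 1),
             (5, 5), (12, 18)],
            (78, 86), has_propeptide=False, basicity_bias=0.2,
        ),
    ]


def write_fasta(records: list, path, width: int = 60) -> None:
    """Deterministic FASTA writer (fixed wrap, LF endings)."""
    with open(path, "w", newline="\n") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


TRUTH_COLUMNS = [
    "est_id", "transcript_id", "category", "family",
    "signal_start", "signal_end", "pro_start", "pro_end",
    "mature_start", "mature_end", "amidation_tail", "skeleton",
]


def truth_table_rows(truths: list) -> list:
    """Flatten ESTTruth objects into TSV-ready rows (TRUTH_COLUMNS order)."""
    rows = []
    for t in truths:
        sig = t.signal_range or ("", "")
        pro = t.propeptide_range or ("", "")
        mat = t.mature_range or ("", "")
        rows.append([
            t.est_id, t.transcript_id, t.category, t.family,
            sig[0], sig[1], pro[0], pro[1], mat[0], mat[1],
            t.amidation_tail, t.skeleton_rendering,
        ])
    return rows
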