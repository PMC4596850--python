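"""Toxin-precursor parsing: ORF finding, signal/propeptide/mature splitting,
PQM cleavage, and C-terminal amidation processing.

A precursor is parsed into three contiguous regions (1-based inclusive
coordinates that tile the sequence):

    signal peptide (16-25 aa) | propeptide (12-38 aa, optional) | mature

The propeptide, when present, ends at a Processing Quadruplet Motif:
arginine at the cleavage position with at least one acidic residue among the
three preceding positions. Mature peptides ending in G / GK / GR have that
tail trimmed and are flagged as amidated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

__all__ = [
    "OrfResult",
    "ToxinPrecursor",
    "NoOrfError",
    "SignalNotFoundError",
    "find_orf",
    "split_signal",
    "find_pqm_cleavage",
    "detect_amidation",
    "parse_precursor",
    "KYTE_DOOLITTLE",
    "SIGNAL_CUT_RESIDUES",
]

SIGNAL_MIN, SIGNAL_MAX = 16, 25
PRO_MIN, PRO_MAX = 12, 38
MATURE_MIN = 33
MIN_ORF_CODONS = 30

#: residues admissible at the last position of a signal peptide (small/polar
#: residues typical of signal-peptidase -1 sites)
SIGNAL_CUT_RESIDUES = frozenset("AGSCT")

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}


class NoOrfError(ValueError):
    """No open reading frame of sufficient length; record is skipped."""


class SignalNotFoundError(ValueError):
    """No admissible signal-peptide cut; precursor flagged unparsed-signal."""


@dataclass(frozen=True)
class OrfResult:
    aa_sequence: str
    frame: int          # 0, 1 or 2
    nt_start: int       # 0-based, position of the A of ATG
    nt_end: int         # 0-based exclusive, past the stop codon


@dataclass
class ToxinPrecursor:
    """Parsed precursor; all ranges 1-based inclusive on the aa sequence."""

    id: str
    aa_sequence: str
    signal_range: tuple
    propeptide_range: Optional[tuple]
    mature_range: tuple            # genetic mature region incl. amidation tail
    amidated: bool
    trimmed_tail: str              # "", "G", "GK" or "GR"

    @property
    def signal(self) -> str:
        a, b = self.signal_range
        return self.aa_sequence[a - 1:b]

    @property
    def propeptide(self) -> Optional[str]:
        if self.propeptide_range is None:
            return None
        a, b = self.propeptide_range
        return self.aa_sequence[a - 1:b]

    @property
    def mature_genetic(self) -> str:
        a, b = self.mature_range
        return self.aa_sequence[a - 1:b]

    @property
    def mature(self) -> str:
        """Processed mature peptide (amidation tail removed)."""
        m = self.mature_genetic
        return m[:len(m) - len(self.trimmed_tail)] if self.trimmed_tail else m


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

def find_orf(nt_sequence: str, min_codons: int = MIN_ORF_CODONS) -> OrfResult:
    """Longest ATG->stop ORF across the three forward frames.

    Ties are broken by the earliest start position in the sequence. Raises
    :class:`NoOrfError` when no ORF reaches ``min_codons`` amino acids.
    """
    seq = nt_sequence.upper()
    best: Optional[OrfResult] = None
    for frame in range(3):
        trimmed = seq[frame:]
        trimmed = trimmed[:len(trimmed) - len(trimmed) % 3]
        if len(trimmed) < 3:
            continue
        protein = str(Seq(trimmed).translate())
        pos = 0
        while True:
            m = protein.find("M", pos)
            if m == -1:
                break
            stop = protein.find("*", m)
            if stop == -1:
                break
            aa = protein[m:stop]
            if len(aa) >= min_codons:
                nt_start = frame + 3 * m
                nt_end = frame + 3 * (stop + 1)
                cand = OrfResult(aa, frame, nt_start, nt_end)
                if (
                    best is None
                    or len(cand.aa_sequence) > len(best.aa_sequence)
                    or (
                        len(cand.aa_sequence) == len(best.aa_sequence)
                        and cand.nt_start < best.nt_start
                    )
                ):
                    best = cand
            pos = m + 1
        # no explicit skip of nested starts: all M's are tried
    if best is None:
        raise NoOrfError(f"no ORF of >= {min_codons} codons")
    return best


# ---------------------------------------------------------------------------
# region splitting
# ---------------------------------------------------------------------------

def split_signal(precursor_aa: str, site: Optional[int] = None) -> tuple:
    """Split off the signal peptide; returns (signal, remainder).

    If ``site`` (length of the signal) is supplied — e.g. from an external
    predictor — it is validated against the 16-25 aa bounds. Otherwise a
    heuristic picks the cut in [16, 25] maximizing the mean Kyte–Doolittle
    hydrophobicity of the prefix, restricted to cuts whose last residue is a
    small/polar signal-peptidase residue; ties go to the smallest position.
    """
    if len(precursor_aa) <= 35:
        raise ValueError("precursor too short to split (need > 35 aa)")
    if site is not None:
        if not SIGNAL_MIN <= site <= SIGNAL_MAX:
            raise ValueError(
                f"signal site {site} outside [{SIGNAL_MIN}, {SIGNAL_MAX}]"
            )
        return precursor_aa[:site], precursor_aa[site:]
    best_site, best_score = None, None
    hi = min(SIGNAL_MAX, len(precursor_aa) - 1)
    for s in range(SIGNAL_MIN, hi + 1):
        if precursor_aa[s - 1] not in SIGNAL_CUT_RESIDUES:
            continue
        score = sum(KYTE_DOOLITTLE.get(aa, 0.0) for aa in precursor_aa[:s]) / s
        if best_score is None or score > best_score:
            best_site, best_score = s, score
    if best_site is None:
        raise SignalNotFoundError("no admissible signal cut in [16, 25]")
    return precursor_aa[:best_site], precursor_aa[best_site:]


def find_pqm_cleavage(
    remainder_aa: str,
    acidic: str = "E",
    min_mature: int = MATURE_MIN,
) -> tuple:
    """Locate the propeptide/mature boundary at the last PQM in the window.

    Scans positions ``p`` with 12 <= p <= 38 and cleaves after the last
    position where residue ``p`` is R and at least one of residues p-1, p-2,
    p-3 belongs to ``acidic`` ({E} by default, {E, D} optionally). Returns
    ``(propeptide, mature)``; ``(None, remainder)`` when no propeptide is
    found or the implied mature peptide would fall below ``min_mature`` aa.
    """
    if not remainder_aa:
        raise ValueError("empty remainder")
    acidic_set = set(acidic)
    cut = None
    for p in range(PRO_MIN, min(PRO_MAX, len(remainder_aa)) + 1):
        if remainder_aa[p - 1] != "R":
            continue
        window = remainder_aa[max(0, p - 4):p - 1]
        if acidic_set & set(window):
            cut = p
    if cut is None or len(remainder_aa) - cut < min_mature:
        return None, remainder_aa
    return remainder_aa[:cut], remainder_aa[cut:]


def detect_amidation(mature_aa: str) -> tuple:
    """Trim a C-terminal amidation signal; returns (processed, flag, tail).

    Two-letter signals GK / GR take precedence over the single G.
    """
    if len(mature_aa) < 4:
        return mature_aa, False, ""
    if mature_aa.endswith(("GK", "GR")):
        return mature_aa[:-2], True, mature_aa[-2:]
    if mature_aa.endswith("G"):
        return mature_aa[:-1], True, "G"
    return mature_aa, False, ""


def parse_precursor(
    record_id: str,
    aa_sequence: str,
    signal_site: Optional[int] = None,
    acidic: str = "E",
) -> ToxinPrecursor:
    """Full region parse of one precursor amino-acid sequence."""
    signal, remainder = split_signal(aa_sequence, site=signal_site)
    propeptide, mature_genetic = find_pqm_cleavage(remainder, acidic=acidic)
    _, amidated, tail = detect_amidation(mature_genetic)
    s = len(signal)
    if propeptide is None:
        pro_range = None
        mature_start = s + 1
    else:
        pro_range = (s + 1, s + len(propeptide))
        mature_start = s + len(propeptide) + 1
    return ToxinPrecursor(
        id=record_id,
        aa_sequence=aa_sequence,
        signal_range=(1, s),
        propeptide_range=pro_range,
        mature_range=(mature_start, len(aa_sequence)),
        amidated=amidated,
        trimmed_tail=tail,
    )
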