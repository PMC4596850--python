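"""Theoretical peptide masses, isoelectric points, and MALDI-style matching.

Masses follow the usual residue-mass bookkeeping: sum of residue masses plus
one water, minus two hydrogens per disulfide bond, and an OH->NH2 correction
for C-terminally amidated peptides. Matching against an observed mass list is
greedy one-to-one by ascending absolute error, which is the "closest match"
convention of linear-mode MALDI-TOF comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "MassSpec",
    "MassMatch",
    "MatchResult",
    "peptide_mass",
    "compute_pi",
    "load_pka_table",
    "match_masses",
    "MONO_RESIDUE_MASS",
    "AVG_RESIDUE_MASS",
]

MONO_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

AVG_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONO = 18.010565
WATER_AVG = 18.0153
# mass removed per disulfide bond (2 x H)
DISULFIDE_MONO = 2.01565
DISULFIDE_AVG = 2.0159
# OH -> NH2 at the C-terminus
AMIDATION_MONO = -0.98402
AMIDATION_AVG = -0.9847


@dataclass(frozen=True)
class MassSpec:
    """How a theoretical mass is to be computed."""

    mode: str = "average"  # "mono" | "average"
    n_disulfides: int = 0
    amidated: bool = False

    def __post_init__(self):
        if self.mode not in ("mono", "average"):
            raise ValueError(f"unknown mass mode {self.mode!r}")
        if self.n_disulfides < 0:
            raise ValueError("n_disulfides must be >= 0")


def peptide_mass(aa_sequence: str, spec: MassSpec = MassSpec()) -> float:
    """Theoretical mass in Daltons of a (possibly oxidized/amidated) peptide."""
    if not aa_sequence:
        raise ValueError("empty sequence")
    table = MONO_RESIDUE_MASS if spec.mode == "mono" else AVG_RESIDUE_MASS
    total = WATER_MONO if spec.mode == "mono" else WATER_AVG
    for pos, aa in enumerate(aa_sequence, start=1):
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {pos}") from None
    n_cys = aa_sequence.count("C")
    if spec.n_disulfides > n_cys // 2:
        raise ValueError(
            f"{spec.n_disulfides} disulfides exceed capacity of "
            f"{n_cys} cysteine(s)"
        )
    if spec.mode == "mono":
        total -= spec.n_disulfides * DISULFIDE_MONO
        if spec.amidated:
            total += AMIDATION_MONO
    else:
        total -= spec.n_disulfides * DISULFIDE_AVG
        if spec.amidated:
            total += AMIDATION_AVG
    return total


# ---------------------------------------------------------------------------
# isoelectric point
# ---------------------------------------------------------------------------

def load_pka_table(name: str = "bjellqvist") -> dict:
    """Load a named pKa set shipped with the package."""
    path = resources.files("venomest.data") / f"pka_{name}.json"
    with path.open() as fh:
        return json.load(fh)


def _net_charge(ph: float, pos_groups, neg_groups) -> float:
    z = 0.0
    for pka, count in pos_groups:
        z += count / (1.0 + 10.0 ** (ph - pka))
    for pka, count in neg_groups:
        z -= count / (1.0 + 10.0 ** (pka - ph))
    return z


def compute_pi(
    aa_sequence: str,
    pka_table: dict | None = None,
    tolerance: float = 1e-4,
) -> float:
    """Isoelectric point by bisection of the Henderson–Hasselbalch net charge.

    The charge model is composition-only (free N-/C-termini plus ionizable
    side chains), so the result is invariant to residue order.
    """
    if not aa_sequence:
        raise ValueError("empty sequence")
    table = pka_table if pka_table is not None else load_pka_table()
    pos = [(table["nterm_by_residue"].get(aa_sequence[0],
                                          table["nterm_default"]), 1)]
    neg = [(table["cterm_by_residue"].get(aa_sequence[-1],
                                          table["cterm_default"]), 1)]
    for aa, pka in table["positive"].items():
        n = aa_sequence.count(aa)
        if n:
            pos.append((pka, n))
    for aa, pka in table["negative"].items():
        n = aa_sequence.count(aa)
        if n:
            neg.append((pka, n))
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        z = _net_charge(mid, pos, neg)
        if abs(z) < tolerance and hi - lo < 1e-4:
            return mid
        if z > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# observed-mass reconciliation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassMatch:
    peptide_id: str
    calculated_mass: float
    observed_mass: float

    @property
    def delta(self) -> float:
        return self.observed_mass - self.calculated_mass


@dataclass
class MatchResult:
    matches: list
    unmatched_peptides: list   # ids
    unmatched_observed: list   # masses


def match_masses(
    calculated: Sequence[tuple],
    observed: Iterable[float],
    tolerance: float = 1.0,
) -> MatchResult:
    """Greedy one-to-one closest matching of calculated vs observed masses.

    Candidate pairs within ``tolerance`` are taken in order of ascending
    absolute error, ties broken by peptide id then observed mass, so the
    result is independent of input ordering.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    observed = sorted(observed)
    pairs = []
    for pid, calc in calculated:
        for obs_idx, obs in enumerate(observed):
            err = abs(obs - calc)
            if err <= tolerance:
                pairs.append((err, pid, obs, obs_idx, calc))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_pep, used_obs = set(), set()
    matches = []
    for err, pid, obs, obs_idx, calc in pairs:
        if pid in used_pep or obs_idx in used_obs:
            continue
        used_pep.add(pid)
        used_obs.add(obs_idx)
        matches.append(MassMatch(pid, calc, obs))
    matches.sort(key=lambda m: m.peptide_id)
    unmatched_pep = sorted(pid for pid, _ in calculated if pid not in used_pep)
    unmatched_obs = [
        obs for idx, obs in enumerate(observed) if idx not in used_obs
    ]
    return MatchResult(matches, unmatched_pep, unmatched_obs)
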