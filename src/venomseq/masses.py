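"""Monoisotopic mass arithmetic for disulfide-rich venom peptides.

All masses are monoisotopic daltons.  A peptide's neutral mass is composed
from residue masses plus a water terminus, adjusted for three kinds of
modification state that matter for MALDI-TOF characterisation of spider
toxins:

* disulfide bonds (each bond removes two hydrogens relative to the fully
  reduced peptide),
* ethanolyl capping of reduced cysteine thiols by iodoethanol (adds
  C2H4O, 44.026 Da, per cysteine; measured from the oxidised peptide the
  apparent per-cysteine step is ~45 Da because reduction first adds one H),
* C-terminal amidation (CONH2 replaces COOH, -0.984 Da).

Average masses are deliberately not implemented: the workflow this package
models reads reflector-mode monoisotopic M+H+ ions only.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "RESIDUE_MASS",
    "WATER",
    "PROTON",
    "AMMONIA",
    "AMIDE_DELTA",
    "ETHANOLYL_ADDITION",
    "DISULFIDE_DELTA",
    "HYDROGEN",
    "CysState",
    "CTerminus",
    "PeptideSpec",
    "residue_mass",
    "peptide_mass",
    "mh_ion",
    "alkylation_shift",
    "infer_cys_count",
]

# Monoisotopic residue (i.e. dehydrated) masses for the 20 standard amino
# acids, summed from CODATA atomic masses.  Hard-coded so the table is
# immutable and hermetic; Ile/Leu are isobaric by construction.
RESIDUE_MASS: Mapping[str, float] = MappingProxyType({
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
})

WATER = 18.010565
PROTON = 1.007276
AMMONIA = 17.026549
HYDROGEN = 1.007825
#: CONH2 replacing COOH at the C terminus.
AMIDE_DELTA = -0.984016
#: C2H4O added to each reduced cysteine thiol by iodoethanol.
ETHANOLYL_ADDITION = 44.026215
#: Per disulfide bond, relative to the fully reduced peptide (loss of 2 H).
DISULFIDE_DELTA = -2.015650


class CysState(str, enum.Enum):
    """Cysteine chemistry of a peptide as it sits in the spectrometer."""

    OXIDIZED = "oxidized"     # disulfide-bonded (native)
    REDUCED = "reduced"       # free thiols
    ETHANOLYL = "ethanolyl"   # reduced and capped with iodoethanol


class CTerminus(str, enum.Enum):
    FREE_ACID = "free_acid"
    AMIDE = "amide"


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence plus the modification state its mass depends on.

    Parameters
    ----------
    sequence
        One-letter residue string (positions are 1-based everywhere in this
        package).
    n_disulfides
        Number of disulfide bonds; only meaningful with oxidized cysteines.
    cys_state
        One of :class:`CysState`.
    c_terminus
        One of :class:`CTerminus`.
    """

    sequence: str
    n_disulfides: int = 0
    cys_state: CysState = CysState.REDUCED
    c_terminus: CTerminus = CTerminus.FREE_ACID

    def __post_init__(self) -> None:
        object.__setattr__(self, "cys_state", CysState(self.cys_state))
        object.__setattr__(self, "c_terminus", CTerminus(self.c_terminus))
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - set(RESIDUE_MASS)
        if bad:
            raise ValueError(f"unknown residue code(s): {sorted(bad)}")
        if self.n_disulfides < 0:
            raise ValueError("n_disulfides must be >= 0")
        if 2 * self.n_disulfides > self.n_cys:
            raise ValueError(
                f"{self.n_disulfides} disulfides need "
                f"{2 * self.n_disulfides} Cys but sequence has {self.n_cys}"
            )
        if self.cys_state is CysState.ETHANOLYL and self.n_disulfides:
            raise ValueError("ethanolyl-capped peptides carry no disulfides")

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")

    def __len__(self) -> int:
        return len(self.sequence)

    def replace(self, **kw) -> "PeptideSpec":
        from dataclasses import replace as _replace
        return _replace(self, **kw)


def residue_mass(code: str) -> float:
    """Monoisotopic residue mass for a one-letter code.

    >>> round(residue_mass('F'), 2)
    147.07
    """
    try:
        return RESIDUE_MASS[code]
    except KeyError:
        raise KeyError(f"unknown residue code: {code!r}") from None


def peptide_mass(spec: PeptideSpec) -> float:
    """Neutral monoisotopic mass of a peptide in its modification state."""
    m = sum(RESIDUE_MASS[a] for a in spec.sequence) + WATER
    m += spec.n_disulfides * DISULFIDE_DELTA
    if spec.cys_state is CysState.ETHANOLYL:
        m += spec.n_cys * ETHANOLYL_ADDITION
    if spec.c_terminus is CTerminus.AMIDE:
        m += AMIDE_DELTA
    return m


def mh_ion(neutral: float) -> float:
    """Singly protonated ion m/z for a neutral mass."""
    if neutral <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral}")
    return neutral + PROTON


def alkylation_shift(n_cys: int, from_state: CysState | str = CysState.OXIDIZED) -> float:
    """Mass gained when *n_cys* cysteines are reduced and ethanolyl-capped.

    Measured from the reduced peptide the step is 44.026 Da per Cys; from the
    native oxidised peptide each Cys additionally gains the hydrogen released
    on disulfide reduction, hence 45.034 Da per Cys (six cysteines: 270 Da).
    """
    from_state = CysState(from_state)
    if n_cys < 0:
        raise ValueError("n_cys must be >= 0")
    if from_state is CysState.OXIDIZED:
        if n_cys % 2:
            raise ValueError(
                "odd cysteine count is inconsistent with full disulfide pairing"
            )
        return n_cys * (ETHANOLYL_ADDITION + HYDROGEN)
    if from_state is CysState.REDUCED:
        return n_cys * ETHANOLYL_ADDITION
    raise ValueError(f"cannot alkylate from state {from_state}")


def infer_cys_count(
    observed_shift: float,
    from_state: CysState | str = CysState.OXIDIZED,
    tolerance: float = 1.0,
    max_cys: int = 20,
) -> tuple[int, int]:
    """Cysteine (and disulfide) count explaining an observed alkylation shift.

    Scans n = 0..*max_cys* (even n only when starting from the oxidised,
    fully paired peptide) and returns the count whose theoretical shift is
    nearest the observation, provided the residual is within *tolerance* Da.

    Returns
    -------
    (n_cys, n_disulfides) — n_disulfides is n_cys // 2 when starting from the
    oxidised peptide, else 0.
    """
    from_state = CysState(from_state)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if from_state is CysState.OXIDIZED:
        candidates = range(0, max_cys + 1, 2)
    else:
        candidates = range(0, max_cys + 1)
    best = min(candidates, key=lambda n: abs(observed_shift - alkylation_shift(n, from_state)))
    resid = observed_shift - alkylation_shift(best, from_state)
    if abs(resid) > tolerance:
        raise ValueError(
            f"no consistent cysteine count: best n={best} leaves "
            f"residual {resid:+.3f} Da (> {tolerance} Da)"
        )
    n_ss = best // 2 if from_state is CysState.OXIDIZED else 0
    return best, n_ss
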