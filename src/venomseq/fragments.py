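"""Theoretical fragment generation.

Covers the four fragment families the MALDI workflow interprets:

* ISD c-ion ladders (reading frame for de novo sequence tags),
* tryptic digests with missed cleavages (peptide mass fingerprints),
* b/y MS/MS series for fragment verification,
* carboxypeptidase-Y C-terminal truncation ladders.

c ions are modeled as singly protonated c species (b + NH3); z and a ions
are not generated.  Positions are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .masses import (
    AMMONIA,
    PROTON,
    RESIDUE_MASS,
    WATER,
    AMIDE_DELTA,
    ETHANOLYL_ADDITION,
    CTerminus,
    CysState,
    PeptideSpec,
    mh_ion,
    peptide_mass,
)

__all__ = [
    "Fragment",
    "IonSeries",
    "c_ion_series",
    "tryptic_digest",
    "by_ion_series",
    "cpy_ladder",
]

DEFAULT_MAX_MISSED = 2


@dataclass(frozen=True)
class Fragment:
    """A contiguous stretch of a parent peptide with its own mass state."""

    parent_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    missed_cleavages: int
    spec: PeptideSpec
    mh: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("fragment positions must satisfy 1 <= start <= end")


@dataclass(frozen=True)
class IonSeries:
    """An ordered N- or C-terminal ion ladder (m/z strictly increasing)."""

    series: str  # 'c', 'b' or 'y'
    ions: tuple[tuple[int, float], ...]  # (index, m/z)

    def mz(self) -> list[float]:
        return [mz for _, mz in self.ions]


def _cys_addition(spec: PeptideSpec) -> float:
    return ETHANOLYL_ADDITION if spec.cys_state is CysState.ETHANOLYL else 0.0


def _prefix_masses(spec: PeptideSpec) -> list[float]:
    """Cumulative residue-mass sums (with Cys-state addition), prefix i = 1..n."""
    add = _cys_addition(spec)
    total = 0.0
    out = []
    for a in spec.sequence:
        total += RESIDUE_MASS[a] + (add if a == "C" else 0.0)
        out.append(total)
    return out


def c_ion_series(spec: PeptideSpec, include_full: bool = False) -> IonSeries:
    """Theoretical singly protonated c ions for i = 1..n-1 (optionally n).

    c_i = sum of residues 1..i + NH3 + proton; consecutive c ions therefore
    differ by exactly one residue mass, which is what ladder reading exploits.
    Disulfides are ignored: ISD spectra of reductive-matrix preparations are
    read as if the peptide were reduced.
    """
    if len(spec) < 2:
        raise ValueError("c-ion series needs at least 2 residues")
    prefixes = _prefix_masses(spec)
    last = len(spec) if include_full else len(spec) - 1
    ions = tuple(
        (i, prefixes[i - 1] + AMMONIA + PROTON) for i in range(1, last + 1)
    )
    return IonSeries("c", ions)


def tryptic_digest(
    spec: PeptideSpec,
    max_missed: int = DEFAULT_MAX_MISSED,
    parent_id: str = "parent",
) -> list[Fragment]:
    """In-silico trypsin digest: cleave after K/R except before P.

    Emits every fragment with 0..*max_missed* internal missed cleavages.
    Fragments inherit the parent's cysteine state; only the C-terminal
    fragment inherits the parent's amidation, all others are free acids.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = spec.sequence
    n = len(seq)
    # cut points: index i means a cut between residue i and i+1 (1-based)
    cuts = [
        i for i in range(1, n)
        if seq[i - 1] in "KR" and seq[i] != "P"
    ]
    bounds = [0] + cuts + [n]  # minimal-fragment boundaries as 0-based offsets
    frags: list[Fragment] = []
    npieces = len(bounds) - 1
    for i in range(npieces):
        for j in range(i, min(i + max_missed + 1, npieces)):
            start, end = bounds[i] + 1, bounds[j + 1]
            cterm = spec.c_terminus if end == n else CTerminus.FREE_ACID
            sub = PeptideSpec(
                seq[start - 1:end],
                n_disulfides=0,
                cys_state=spec.cys_state,
                c_terminus=cterm,
            )
            frags.append(
                Fragment(parent_id, start, end, j - i, sub, mh_ion(peptide_mass(sub)))
            )
    return frags


def by_ion_series(spec: PeptideSpec) -> tuple[IonSeries, IonSeries]:
    """Theoretical singly protonated b and y ions (i, j = 1..n-1).

    b_i carries the N terminus, y_j the C terminus; for an amidated parent
    every y ion (and no b ion) carries the amide mass offset.  The series
    satisfy the complementarity identity b_i + y_{n-i} = MH+ + proton.
    """
    if len(spec) < 2:
        raise ValueError("b/y series need at least 2 residues")
    n = len(spec)
    prefixes = _prefix_masses(spec)
    total = prefixes[-1]
    amide = AMIDE_DELTA if spec.c_terminus is CTerminus.AMIDE else 0.0
    b = tuple((i, prefixes[i - 1] + PROTON) for i in range(1, n))
    y = tuple(
        (j, total - prefixes[n - j - 1] + WATER + PROTON + amide)
        for j in range(1, n)
    )
    return IonSeries("b", b), IonSeries("y", y)


def cpy_ladder(
    spec: PeptideSpec, depth: int
) -> list[tuple[int, float, float]]:
    """Carboxypeptidase-Y truncation ladder.

    Entry k is the parent with its k C-terminal residues removed (the
    truncated species are free acids: hydrolysis regenerates a carboxylate).
    The removed-residue mass of step 1 includes the amide offset when the
    parent is amidated — an amidated terminal residue reads ~1 Da light,
    which is exactly the diagnostic CPY ladder sequencing relies on.

    Returns
    -------
    list of (k, neutral mass after k removals, mass removed at step k)
    """
    n = len(spec)
    if not 1 <= depth < n:
        raise ValueError("depth must satisfy 1 <= depth < len(sequence)")
    out = []
    prev = peptide_mass(spec)
    for k in range(1, depth + 1):
        trunc = PeptideSpec(
            spec.sequence[: n - k],
            n_disulfides=0,
            cys_state=spec.cys_state,
            c_terminus=CTerminus.FREE_ACID,
        )
        m = peptide_mass(trunc)
        out.append((k, m, prev - m))
        prev = m
    return out
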