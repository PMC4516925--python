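"""Inference from observed peak lists.

This module turns MALDI-TOF observations into sequence evidence:

* :func:`read_isd_ladder` reads in-source-decay c-ion ladders into partial
  sequence tags (the de novo step),
* :func:`match_pmf` compares an observed tryptic peptide mass fingerprint
  against a theoretical digest,
* :func:`detect_amidation` turns an observed-vs-predicted M+H+ deficit into
  a C-terminal amidation verdict,
* :func:`substitution_from_delta` lists single-residue substitutions
  consistent with a mass difference between two paralogous peptides,
* :func:`interpret_cpy` reads a carboxypeptidase-Y time-course into the
  C-terminal residue sequence and its amidation state,
* :func:`annotate_msms` annotates MS/MS peaks with b/y assignments.

Tolerances are absolute daltons (MALDI-TOF external-calibration regime);
defaults live in :class:`venomseq.config.RunConfig`.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .masses import AMIDE_DELTA, AMMONIA, PROTON, RESIDUE_MASS, PeptideSpec
from .fragments import Fragment, by_ion_series

__all__ = [
    "PeakList",
    "SequenceTag",
    "AmidationCall",
    "PMFResult",
    "CpyReading",
    "MsmsAnnotation",
    "residues_within",
    "residue_pairs_within",
    "read_isd_ladder",
    "match_pmf",
    "detect_amidation",
    "substitution_from_delta",
    "interpret_cpy",
    "annotate_msms",
]

# Sorted (mass, residue) pairs for tolerance lookups; I/L share one mass.
_MASS_RESIDUE = sorted((m, a) for a, m in RESIDUE_MASS.items())
_MIN_RES = _MASS_RESIDUE[0][0]
_MAX_RES = _MASS_RESIDUE[-1][0]


def residues_within(
    delta: float, tolerance: float, cys_addition: float = 0.0
) -> frozenset[str]:
    """All residue codes whose mass is within *tolerance* of *delta*.

    *cys_addition* shifts the cysteine entry (e.g. +44.026 Da when the
    peptide under study is ethanolyl-alkylated; capped Cys is then nearly
    isobaric with Phe, a real ambiguity of CPY ladders on alkylated
    peptides).
    """
    if cys_addition:
        table = sorted(
            (m + (cys_addition if a == "C" else 0.0), a)
            for a, m in RESIDUE_MASS.items()
        )
    else:
        table = _MASS_RESIDUE
    lo = bisect.bisect_left(table, (delta - tolerance, ""))
    hi = bisect.bisect_right(table, (delta + tolerance, "~"))
    return frozenset(a for _, a in table[lo:hi])


def residue_pairs_within(delta: float, tolerance: float) -> list[frozenset[str]]:
    """Unordered residue pairs whose summed mass is within tolerance of delta."""
    out = []
    seen = set()
    for m1, a1 in _MASS_RESIDUE:
        if m1 > delta - _MIN_RES + tolerance:
            break
        for m2, a2 in _MASS_RESIDUE:
            if abs(m1 + m2 - delta) <= tolerance:
                key = frozenset((a1, a2)) if a1 != a2 else frozenset((a1,))
                if key not in seen:
                    seen.add(key)
                    out.append(frozenset((a1, a2)))
    return out


@dataclass(frozen=True)
class PeakList:
    """Observed (m/z, intensity) pairs, sorted ascending, duplicates merged."""

    mz: np.ndarray
    intensity: np.ndarray
    source: str = ""

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[float, float]] | Iterable[float],
        source: str = "",
        merge_tol: float = 1e-4,
    ) -> "PeakList":
        rows = []
        for p in pairs:
            if np.isscalar(p):
                rows.append((float(p), 1.0))
            else:
                mz, inten = p
                rows.append((float(mz), float(inten)))
        if any(mz <= 0 for mz, _ in rows):
            raise ValueError("all m/z values must be positive")
        rows.sort()
        merged: list[list[float]] = []
        for mz, inten in rows:
            if merged and mz - merged[-1][0] < merge_tol:
                merged[-1][1] += inten
            else:
                merged.append([mz, inten])
        mzs = np.array([m for m, _ in merged])
        ints = np.array([i for _, i in merged])
        return cls(mzs, ints, source)

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class SequenceTag:
    """A partial residue string read from a ladder.

    ``positions`` holds one ambiguity class per residue position (N- to
    C-terminal); isobaric Ile/Leu always co-occur.  A bridged single-peak
    dropout appears as two consecutive positions flagged in ``gap_steps``,
    each carrying the union of the residues from the candidate pairs whose
    summed mass explains the composite step.
    """

    positions: tuple[frozenset[str], ...]
    anchor_mz: float
    residuals: tuple[float, ...]
    gap_steps: tuple[int, ...] = ()  # indices into positions

    def __len__(self) -> int:
        return len(self.positions)

    def as_string(self) -> str:
        out = []
        for cls in self.positions:
            if cls >= {"I", "L"} and len(cls) == 2:
                out.append("I")  # canonical representative for the I/L class
            elif len(cls) == 1:
                out.append(next(iter(cls)))
            else:
                out.append("[" + "".join(sorted(cls)) + "]")
        return "".join(out)

    def matches(self, sequence: str) -> bool:
        if len(sequence) != len(self.positions):
            return False
        return all(_residue_in_class(r, c) for r, c in zip(sequence, self.positions))

    def segments(self, min_len: int = 5) -> list["SequenceTag"]:
        """Gap-free sub-tags, longest first.

        Splitting at bridged-gap positions yields the runs of directly
        observed single-residue steps; these are the trustworthy parts of a
        corrupted ladder read and are searched independently.
        """
        cut = set(self.gap_steps)
        runs: list[list[int]] = [[]]
        for i in range(len(self.positions)):
            if i in cut:
                if runs[-1]:
                    runs.append([])
            else:
                runs[-1].append(i)
        out = []
        for run in runs:
            if len(run) >= min_len:
                out.append(
                    SequenceTag(
                        tuple(self.positions[i] for i in run),
                        self.anchor_mz,
                        (),
                        (),
                    )
                )
        out.sort(key=len, reverse=True)
        return out


def _residue_in_class(residue: str, cls: frozenset[str]) -> bool:
    if residue in cls:
        return True
    # I and L are indistinguishable by mass
    if residue == "I" and "L" in cls:
        return True
    if residue == "L" and "I" in cls:
        return True
    return False


@dataclass(frozen=True)
class AmidationCall:
    delta: float  # predicted free-acid MH+ − observed MH+
    verdict: str  # 'amide' | 'free_acid' | 'inconclusive'


def read_isd_ladder(
    peaks: PeakList,
    tolerance: float = 0.3,
    min_tag_length: int = 1,
    infer_anchor_residue: bool = True,
) -> list[SequenceTag]:
    """Read sequence tags from a (noisy, gappy) ISD c-ion ladder.

    Builds a directed acyclic graph over peaks: an edge joins two peaks whose
    m/z difference matches a residue mass within *tolerance* (single step) or
    a sum of two residue masses (composite step bridging one dropped peak).
    Maximal-score paths are reported as tags, longest first; a path's score
    prefers more residue positions, then fewer bridged gaps.  When
    *infer_anchor_residue* is set, the first peak of a path is additionally
    interpreted as a c1 ion (residue + NH3 + proton), which when it matches
    prepends one more position — this is how a complete c ladder of an
    n-mer yields an n-residue tag.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    n = len(peaks)
    if n == 0:
        return []
    mz = peaks.mz
    # adjacency: edges[i] = list of (j, positions tuple, residual, n_gaps)
    edges: dict[int, list[tuple[int, tuple[frozenset, ...], float, int]]] = {
        i: [] for i in range(n)
    }
    max_span = 2 * _MAX_RES + tolerance
    for i in range(n):
        for j in range(i + 1, n):
            d = mz[j] - mz[i]
            if d > max_span:
                break
            single = residues_within(d, tolerance)
            if single:
                resid = min(abs(d - RESIDUE_MASS[a]) for a in single)
                edges[i].append((j, (single,), resid, 0))
            elif d > _MAX_RES + tolerance:
                pairs = residue_pairs_within(d, tolerance)
                if pairs:
                    union = frozenset().union(*pairs)
                    resid = min(
                        abs(d - sum(RESIDUE_MASS[a] for a in _pair_list(p)))
                        for p in pairs
                    )
                    edges[i].append((j, (union, union), resid, 1))

    used = [False] * n
    tags: list[SequenceTag] = []
    # repeatedly peel off the best remaining path (paths never share peaks)
    while True:
        # longest-path DP over unused nodes: score = (n_positions, -n_gaps)
        best: list[tuple[int, int]] = [(0, 0)] * n
        back: list[tuple[int, tuple, float, int] | None] = [None] * n
        for i in range(n):
            if used[i]:
                continue
            for j, poscls, resid, gaps in edges[i]:
                if used[j]:
                    continue
                cand = (best[i][0] + len(poscls), best[i][1] + gaps)
                if cand[0] > best[j][0] or (
                    cand[0] == best[j][0] and cand[1] < best[j][1]
                ):
                    best[j] = cand
                    back[j] = (i, poscls, resid, gaps)
        terminals = [
            (best[j][0], -best[j][1], -j)
            for j in range(n)
            if best[j][0] > 0 and not used[j]
        ]
        if not terminals:
            break
        _, _, negj = max(terminals)
        # walk back pointers to recover the path and its per-step classes
        node = -negj
        path_nodes = [node]
        positions: list[frozenset] = []
        residuals: list[float] = []
        gap_idx: list[int] = []
        while back[node] is not None:
            i, poscls, resid, gaps = back[node]
            if gaps:
                gap_idx = [0, 1] + [g + len(poscls) for g in gap_idx]
            else:
                gap_idx = [g + len(poscls) for g in gap_idx]
            positions[:0] = poscls
            residuals.insert(0, resid)
            path_nodes.insert(0, i)
            node = i
        anchor = mz[path_nodes[0]]
        if infer_anchor_residue:
            first = residues_within(anchor - AMMONIA - PROTON, tolerance)
            if first:
                positions.insert(0, first)
                gap_idx = [g + 1 for g in gap_idx]
                residuals.insert(
                    0,
                    min(abs(anchor - AMMONIA - PROTON - RESIDUE_MASS[a]) for a in first),
                )
        if len(positions) >= min_tag_length:
            tags.append(
                SequenceTag(tuple(positions), anchor, tuple(residuals), tuple(gap_idx))
            )
        for p in path_nodes:
            used[p] = True
    tags.sort(key=len, reverse=True)
    return tags


def _pair_list(pair: frozenset[str]) -> list[str]:
    lst = sorted(pair)
    return lst if len(lst) == 2 else lst * 2


@dataclass(frozen=True)
class PMFResult:
    matches: tuple[tuple[float, Fragment, float], ...]  # (observed, fragment, obs−theo)
    unexplained: tuple[float, ...]
    unobserved: tuple[Fragment, ...]

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def match_pmf(
    observed: PeakList, theoretical: Sequence[Fragment], tolerance: float = 0.5
) -> PMFResult:
    """Greedy nearest-mass one-to-one assignment of peaks to digest fragments.

    Candidate (peak, fragment) pairs within *tolerance* are assigned in order
    of increasing absolute residual, ties broken toward the lower-mass
    fragment; each peak and fragment is used at most once.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    cands = []
    for oi, omz in enumerate(observed.mz):
        for fi, frag in enumerate(theoretical):
            r = omz - frag.mh
            if abs(r) <= tolerance:
                cands.append((abs(r), frag.mh, oi, fi, r))
    cands.sort(key=lambda t: (t[0], t[1]))
    used_o: set[int] = set()
    used_f: set[int] = set()
    matches = []
    for _, _, oi, fi, r in cands:
        if oi in used_o or fi in used_f:
            continue
        used_o.add(oi)
        used_f.add(fi)
        matches.append((float(observed.mz[oi]), theoretical[fi], float(r)))
    matches.sort(key=lambda t: t[0])
    unexplained = tuple(
        float(m) for i, m in enumerate(observed.mz) if i not in used_o
    )
    unobserved = tuple(f for i, f in enumerate(theoretical) if i not in used_f)
    return PMFResult(tuple(matches), unexplained, unobserved)


def detect_amidation(
    observed_mh: float,
    predicted_free_acid_mh: float,
    amide_window: tuple[float, float] = (0.6, 1.3),
    free_acid_tol: float = 0.3,
) -> AmidationCall:
    """Call C-terminal amidation from an M+H+ deficit.

    Amidation replaces the terminal carboxyl with an amide (−0.984 Da), so
    an observed ion ~1 Da below the free-acid prediction is amide evidence.
    The default amide window [0.6, 1.3] Da brackets that offset with slack
    for external MALDI calibration.
    """
    if observed_mh <= 0 or predicted_free_acid_mh <= 0:
        raise ValueError("masses must be positive")
    delta = predicted_free_acid_mh - observed_mh
    if abs(delta) <= free_acid_tol:
        verdict = "free_acid"
    elif amide_window[0] <= delta <= amide_window[1]:
        verdict = "amide"
    else:
        verdict = "inconclusive"
    return AmidationCall(delta, verdict)


def substitution_from_delta(
    delta: float, tolerance: float = 0.5
) -> set[tuple[str, str]]:
    """Single-residue substitutions consistent with a mass difference.

    Returns all ordered pairs (a, b), a != b, with mass(b) − mass(a) within
    *tolerance* of *delta*.  Isobaric pairs (Ile/Leu) are excluded: a zero
    mass difference carries no substitution signal.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    out = set()
    for a, ma in RESIDUE_MASS.items():
        for b, mb in RESIDUE_MASS.items():
            if a == b or mb == ma:
                continue
            if abs(mb - ma - delta) <= tolerance:
                out.add((a, b))
    return out


@dataclass(frozen=True)
class CpyReading:
    """C-terminal sequence evidence from a CPY time course.

    ``residues`` is ordered from the C terminus inward: element 0 is the
    terminal residue (ambiguity class), element 1 the penultimate one, and
    so on.  A step whose mass matches no residue is reported in ``gaps`` as
    (step index, unexplained mass) and holds an empty class in ``residues``.
    """

    residues: tuple[frozenset[str], ...]
    step_masses: tuple[float, ...]
    verdict: str | None  # amidation verdict for the terminal residue
    gaps: tuple[tuple[int, float], ...] = ()


def interpret_cpy(
    series: Sequence[PeakList],
    tolerance: float = 0.3,
    merge_tol: float = 0.25,
    cys_addition: float = 0.0,
) -> CpyReading:
    """Read a carboxypeptidase-Y truncation time course.

    Pools truncation masses across all time points (an exopeptidase ladder
    accumulates; later aliquots still contain earlier species), merges peaks
    within *merge_tol*, sorts descending and reads consecutive differences
    as removed-residue masses.  The first (C-terminal) step is matched both
    against plain residue masses and residue + amide offset; the verdict is
    ``amide`` when only the amidated interpretation fits, ``free_acid`` when
    only the plain one does, ``inconclusive`` when both do.  Pass
    ``cys_addition=ETHANOLYL_ADDITION`` when the digested peptide carries
    capped cysteines (the usual case: CPY is run on the reduced/alkylated
    peptide).
    """
    if len(series) < 2:
        raise ValueError("need at least two time points")
    all_mz = sorted(m for pl in series for m in pl.mz)
    pooled: list[float] = []
    group: list[float] = []
    for m in all_mz:
        if group and m - group[-1] > merge_tol:
            pooled.append(float(np.mean(group)))
            group = []
        group.append(m)
    if group:
        pooled.append(float(np.mean(group)))
    pooled.sort(reverse=True)
    if len(pooled) < 2:
        return CpyReading((), (), None)
    residues: list[frozenset[str]] = []
    steps: list[float] = []
    gaps: list[tuple[int, float]] = []
    verdict: str | None = None
    for k in range(len(pooled) - 1):
        d = pooled[k] - pooled[k + 1]
        steps.append(d)
        plain = residues_within(d, tolerance, cys_addition)
        if k == 0:
            amidated = residues_within(d - AMIDE_DELTA, tolerance, cys_addition)
            if amidated and not plain:
                verdict = "amide"
            elif plain and not amidated:
                verdict = "free_acid"
            elif plain and amidated:
                verdict = "inconclusive"
            # the terminal class admits both readings (e.g. Glu-amide is
            # isobaric with Gln); the verdict records which applied
            plain = plain | amidated
        if plain:
            residues.append(plain)
        else:
            residues.append(frozenset())
            gaps.append((k, d))
    return CpyReading(tuple(residues), tuple(steps), verdict, tuple(gaps))


@dataclass(frozen=True)
class MsmsAnnotation:
    assignments: tuple[tuple[float, str, int, float], ...]  # (mz, series, index, resid)
    coverage: float  # fraction of backbone bonds supported by b or y ions


def annotate_msms(
    precursor: PeptideSpec, peaks: PeakList, tolerance: float = 0.3
) -> MsmsAnnotation:
    """Match MS/MS peaks against the theoretical b/y series of a precursor.

    Coverage counts backbone bonds i (1..n−1) supported by a matched b_i or
    y_{n−i} ion, divided by n−1.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    b, y = by_ion_series(precursor)
    theo = [("b", i, mz) for i, mz in b.ions] + [("y", j, mz) for j, mz in y.ions]
    n = len(precursor)
    assignments = []
    covered: set[int] = set()
    for omz in peaks.mz:
        best = None
        for series, idx, tmz in theo:
            r = omz - tmz
            if abs(r) <= tolerance and (best is None or abs(r) < abs(best[3])):
                best = (float(omz), series, idx, float(r))
        if best is not None:
            assignments.append(best)
            bond = best[2] if best[1] == "b" else n - best[2]
            covered.add(bond)
    coverage = len(covered) / (n - 1)
    return MsmsAnnotation(tuple(assignments), coverage)
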