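"""Cysteine frameworks, pairwise identity, and NaSpTx-family assignment.

Spider NaV-channel toxins fall into sequence-defined NaSpTx families; most
adopt the inhibitor cystine knot (ICK) fold whose hallmark is six cysteines
in the C-C-CC-C-C framework (cysteines 3 and 4 adjacent, no other adjacent
pair).  Family assignment here is nearest-reference by global pairwise
identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align

__all__ = [
    "CysFramework",
    "detect_framework",
    "pairwise_identity",
    "assign_family",
    "FamilyAssignment",
    "load_reference_families",
]


@dataclass(frozen=True)
class CysFramework:
    positions: tuple[int, ...]  # 1-based cysteine positions
    framework: str              # e.g. "C-C-CC-C-C"
    loop_lengths: tuple[int, ...]
    is_ick_pattern: bool


def detect_framework(sequence: str) -> CysFramework:
    """Derive the cysteine framework string and check for the ICK pattern.

    ``is_ick_pattern`` is True iff the sequence has exactly six cysteines
    whose only adjacency is between cysteines 3 and 4 (C-C-CC-C-C).
    """
    positions = tuple(i + 1 for i, a in enumerate(sequence) if a == "C")
    if not positions:
        return CysFramework((), "", (), False)
    parts = ["C"]
    for prev, cur in zip(positions, positions[1:]):
        if cur == prev + 1:
            parts[-1] += "C"
        else:
            parts.append("C")
    framework = "-".join(parts)
    loops = tuple(cur - prev - 1 for prev, cur in zip(positions, positions[1:]))
    is_ick = len(positions) == 6 and framework == "C-C-CC-C-C"
    return CysFramework(positions, framework, loops, is_ick)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = -1
    a.extend_gap_score = -1
    return a


def pairwise_identity(a: str, b: str) -> tuple[float, int]:
    """Percent identity from a global alignment (match +1, mismatch 0, gap −1).

    Identity = matches / alignment columns × 100; columns include gapped
    positions, a convention recorded in all report metadata.  The first
    optimal alignment in Biopython's deterministic enumeration order is
    used, so results are reproducible.

    Returns (percent identity, alignment length in columns).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    cols = len(s1)
    return 100.0 * matches / cols, cols


def load_reference_families(path=None) -> dict[str, list[tuple[str, str]]]:
    """Load a labeled reference set from FASTA (headers: ``family=NAME``).

    Without *path*, loads the bundled SYNTHETIC placeholder set: random
    ICK-framework sequences at family-typical lengths, carrying NaSpTx
    family labels only so the assignment machinery can be exercised.  Real
    classification requires user-supplied curated reference sequences.
    """
    from Bio import SeqIO

    if path is None:
        from importlib.resources import files

        path = files("venomseq").joinpath("data/nasptx_references.synthetic.fasta")
    refs: dict[str, list[tuple[str, str]]] = {}
    with open(str(path)) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            fam = "unknown"
            for token in rec.description.split():
                if token.startswith("family="):
                    fam = token.split("=", 1)[1]
            refs.setdefault(fam, []).append((rec.id, str(rec.seq).upper()))
    return refs


@dataclass(frozen=True)
class FamilyAssignment:
    family: str | None  # None = unassigned (all identities below threshold)
    best_identity: float
    best_reference: str | None
    per_family_best: Mapping[str, float]


def assign_family(
    query: str,
    references: Mapping[str, Sequence[tuple[str, str]]],
    threshold: float = 40.0,
) -> FamilyAssignment:
    """Assign a toxin to the family of its most similar reference.

    *references* maps family name -> [(reference name, sequence), ...].
    Ties on best identity are broken toward the family with more references
    above *threshold*; if no reference reaches the threshold the query is
    reported unassigned with the best identity found.
    """
    if not references or all(not v for v in references.values()):
        raise ValueError("reference set must be non-empty")
    per_family: dict[str, float] = {}
    above: dict[str, int] = {}
    best: tuple[float, str, str] | None = None  # (identity, family, ref name)
    for family, refs in references.items():
        for name, seq in refs:
            ident, _ = pairwise_identity(query, seq)
            per_family[family] = max(per_family.get(family, 0.0), ident)
            if ident >= threshold:
                above[family] = above.get(family, 0) + 1
            if (
                best is None
                or ident > best[0]
                or (ident == best[0] and above.get(family, 0) > above.get(best[1], 0))
            ):
                best = (ident, family, name)
    assert best is not None
    identity, family, name = best
    if identity < threshold:
        return FamilyAssignment(None, identity, name, per_family)
    return FamilyAssignment(family, identity, name, per_family)
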