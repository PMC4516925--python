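"""Mining toxin precursors from a venom-gland transcriptome.

Three steps take a de novo sequence tag to a fully delimited mature peptide:

1. :func:`extract_orfs` — six-frame stop-to-stop translation of assembled
   contigs into a local protein search database,
2. :func:`tag_search` — ambiguity-aware subsequence search of the tag in
   that database (tags are short and databases small, so an exact search
   with a mismatch budget replaces BLAST: same hits, deterministic),
3. :func:`delimit_mature_by_mass` — sliding mature-peptide boundaries
   around the tag and keeping the windows whose theoretical oxidised M+H+
   matches the observed intact mass, under both free-acid and amidated
   C-terminus hypotheses.  Propeptide cleavage motifs are deliberately not
   modeled; the observed mass is the decisive evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .masses import CTerminus, CysState, PeptideSpec, mh_ion, peptide_mass
from .denovo import SequenceTag, _residue_in_class

__all__ = [
    "Contig",
    "OrfRecord",
    "PrecursorHit",
    "MatureCandidate",
    "extract_orfs",
    "tag_search",
    "tag_search_fuzzy",
    "delimit_mature_by_mass",
]

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str  # A/C/G/T/N

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("contig sequence must be non-empty")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {self.id}: invalid nucleotides {sorted(bad)}")


@dataclass(frozen=True)
class OrfRecord:
    contig_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    protein: str
    met_trimmed: bool = False


@dataclass(frozen=True)
class MatureCandidate:
    start: int  # 1-based inclusive, protein coordinates
    end: int
    c_terminus: CTerminus
    theoretical_mh: float
    residual: float  # theoretical − observed

    @property
    def sequence_slice(self) -> slice:
        return slice(self.start - 1, self.end)


@dataclass(frozen=True)
class PrecursorHit:
    contig_id: str
    frame: int
    protein: str
    tag_start: int  # 1-based inclusive
    tag_end: int
    mismatches: int = 0
    candidates: tuple[MatureCandidate, ...] = ()
    best_rejected_residual: float | None = None


def _translate_frame(nt: str, frame: int) -> str:
    """Translate one frame; codons containing N become 'X' (never match)."""
    if frame > 0:
        s = nt[frame - 1:]
    else:
        s = str(Seq(nt).reverse_complement())[-frame - 1:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    return str(Seq(s).translate())  # standard code; N-codons -> 'X', stops '*'


def extract_orfs(contigs: list[Contig], min_aa: int = 30) -> list[OrfRecord]:
    """Stop-to-stop ORFs of length >= *min_aa* across all six frames.

    Each qualifying segment is emitted untrimmed, and additionally trimmed
    to start at its first Met when one exists (precursor proteins start at
    Met, but stop-to-stop segments of partial contigs may lack one).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    out: list[OrfRecord] = []
    for contig in contigs:
        nt = contig.sequence.upper()
        for frame in (1, 2, 3, -1, -2, -3):
            prot = _translate_frame(nt, frame)
            for segment in prot.split("*"):
                if "X" in segment:
                    # N-containing codons never participate in a match
                    continue
                if len(segment) < min_aa:
                    continue
                out.append(OrfRecord(contig.id, frame, segment))
                mpos = segment.find("M")
                if mpos > 0 and len(segment) - mpos >= min_aa:
                    out.append(
                        OrfRecord(contig.id, frame, segment[mpos:], met_trimmed=True)
                    )
    return out


def tag_search(
    tag: SequenceTag,
    proteins: list[OrfRecord],
    max_mismatch: int = 1,
) -> list[PrecursorHit]:
    """Exact subsequence search of an ambiguous tag over a protein database.

    A position matches when the protein residue is in the tag's ambiguity
    class (Ile and Leu always interchangeable); up to *max_mismatch*
    mismatches are permitted.  Met-trimmed duplicates of the same stop-to-
    stop segment are skipped so each locus is reported once.
    """
    if len(tag) < 5:
        raise ValueError("tag must be at least 5 residues long")
    hits: list[PrecursorHit] = []
    k = len(tag)
    for rec in proteins:
        if rec.met_trimmed:
            continue
        prot = rec.protein
        for s in range(len(prot) - k + 1):
            mism = 0
            for cls, r in zip(tag.positions, prot[s:s + k]):
                if not _residue_in_class(r, cls):
                    mism += 1
                    if mism > max_mismatch:
                        break
            else:
                hits.append(
                    PrecursorHit(rec.contig_id, rec.frame, prot, s + 1, s + k, mism)
                )
    hits.sort(key=lambda h: (h.mismatches, h.contig_id, h.tag_start))
    return hits


def tag_search_fuzzy(
    tag: SequenceTag,
    proteins: list[OrfRecord],
    max_edits: int = 2,
) -> list[PrecursorHit]:
    """Edit-distance tag search tolerating insertions and deletions.

    Long tags read from noisy ladders occasionally carry a phantom residue
    (a chemical-noise peak splitting one ladder step into two); a
    mismatch-only search cannot absorb the resulting register shift, so
    this fallback matches the tag with Levenshtein distance <= *max_edits*
    using edlib.  Ambiguity classes are encoded as placeholder symbols with
    explicit character equivalences.
    """
    import edlib

    if len(tag) < 5:
        raise ValueError("tag must be at least 5 residues long")
    query_chars: list[str] = []
    equalities: list[tuple[str, str]] = [("I", "L")]
    placeholders = iter("abcdefghjkmnopqrstuvwxyz0123456789")
    for cls in tag.positions:
        if len(cls) == 1:
            query_chars.append(next(iter(cls)))
        else:
            ph = next(placeholders)
            query_chars.append(ph)
            equalities.extend((ph, r) for r in cls)
    query = "".join(query_chars)
    hits: list[PrecursorHit] = []
    for rec in proteins:
        if rec.met_trimmed:
            continue
        res = edlib.align(
            query, rec.protein, mode="HW", task="locations",
            k=max_edits, additionalEqualities=equalities,
        )
        if res["editDistance"] < 0:
            continue
        seen: set[tuple[int, int]] = set()
        for s, e in res["locations"]:
            if (s, e) in seen:
                continue
            seen.add((s, e))
            hits.append(
                PrecursorHit(
                    rec.contig_id, rec.frame, rec.protein,
                    s + 1, e + 1, res["editDistance"],
                )
            )
            break  # one location per segment is enough for delimitation
    hits.sort(key=lambda h: (h.mismatches, h.contig_id, h.tag_start))
    return hits


def delimit_mature_by_mass(
    hit: PrecursorHit,
    observed_mh: float,
    n_disulfides: int,
    tolerance: float = 0.25,
    upstream: int = 30,
    downstream: int = 40,
    start_slack: int = 3,
    require_amidation_signal: bool = False,
) -> PrecursorHit:
    """Delimit the mature peptide inside a precursor by intact-mass matching.

    Slides the mature start over [tag_start − *upstream*,
    tag_start + *start_slack*] (the slack absorbs a spuriously prepended
    tag residue) and the end over [tag_end, tag_end + *downstream*]; for
    every window and each
    C-terminus hypothesis computes the oxidised (n_disulfides bonds) M+H+
    and keeps windows within *tolerance* Da of *observed_mh*.  Candidates
    are ranked by absolute residual, then longer length.  With
    *require_amidation_signal*, amide hypotheses additionally need a Gly at
    end+1 (the amidation donor) or the precursor ending at the window.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    prot = hit.protein
    n = len(prot)
    candidates: list[MatureCandidate] = []
    best_reject: float | None = None
    start_hi = min(hit.tag_start + start_slack, hit.tag_end)
    for start in range(max(1, hit.tag_start - upstream), start_hi + 1):
        for end in range(hit.tag_end, min(n, hit.tag_end + downstream) + 1):
            seq = prot[start - 1:end]
            n_ss = min(n_disulfides, seq.count("C") // 2)
            if n_ss != n_disulfides:
                continue  # window cannot host the established disulfide count
            for cterm in (CTerminus.FREE_ACID, CTerminus.AMIDE):
                if cterm is CTerminus.AMIDE and require_amidation_signal:
                    has_gly_donor = end < n and prot[end] == "G"
                    if not (has_gly_donor or end == n):
                        continue
                spec = PeptideSpec(
                    seq, n_disulfides=n_ss, cys_state=CysState.OXIDIZED,
                    c_terminus=cterm,
                )
                mh = mh_ion(peptide_mass(spec))
                resid = mh - observed_mh
                if abs(resid) <= tolerance:
                    candidates.append(MatureCandidate(start, end, cterm, mh, resid))
                elif best_reject is None or abs(resid) < abs(best_reject):
                    best_reject = resid
    # rank: residual, then longer window; exact-tie isobars (e.g. a window
    # shifted across identical flanking residues) resolve toward the window
    # anchored at the tag start, where ISD ladders begin
    candidates.sort(
        key=lambda c: (
            abs(c.residual),
            -(c.end - c.start),
            abs(c.start - hit.tag_start),
        )
    )
    return replace(
        hit,
        candidates=tuple(candidates),
        best_rejected_residual=None if candidates else best_reject,
    )
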