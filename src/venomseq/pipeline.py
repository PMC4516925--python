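"""The full sequence-evidence chain, from peak lists to an annotated mature
peptide.

Mirrors the proteomic workflow for disulfide-rich venom peptides: read a
sequence tag off the ISD ladder, count cysteines from the alkylation mass
shift, find tag-bearing precursors in the transcriptome, delimit the mature
peptide by intact-mass matching, then reconcile the call against the
tryptic PMF, MS/MS fragment coverage and the CPY C-terminal ladder.  The
result is a single evidence report summarising which observations support
each residue-level claim.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .denovo import (
    PeakList,
    annotate_msms,
    detect_amidation,
    interpret_cpy,
    match_pmf,
    read_isd_ladder,
)
from .fragments import tryptic_digest
from .masses import (
    ETHANOLYL_ADDITION,
    CTerminus,
    CysState,
    PeptideSpec,
    infer_cys_count,
    mh_ion,
    peptide_mass,
)
from .transcriptome import (
    Contig,
    delimit_mature_by_mass,
    extract_orfs,
    tag_search,
    tag_search_fuzzy,
)

__all__ = ["EvidenceReport", "run_pipeline"]


@dataclass
class EvidenceReport:
    sequence: str | None
    n_disulfides: int | None
    amidation_verdict: str | None
    cpy_verdict: str | None
    tag: str | None
    tag_length: int
    n_precursor_hits: int
    mass_residual: float | None
    pmf_matched: int
    pmf_total_theoretical: int
    msms_mean_coverage: float | None
    cpy_consistent: bool | None
    notes: list

    def to_dict(self, config: RunConfig | None = None) -> dict:
        d = {
            "sequence": self.sequence,
            "n_disulfides": self.n_disulfides,
            "amidation_verdict": self.amidation_verdict,
            "cpy_verdict": self.cpy_verdict,
            "tag": self.tag,
            "tag_length": self.tag_length,
            "n_precursor_hits": self.n_precursor_hits,
            "mass_residual_Da": self.mass_residual,
            "pmf_matched": self.pmf_matched,
            "pmf_total_theoretical": self.pmf_total_theoretical,
            "msms_mean_coverage": self.msms_mean_coverage,
            "cpy_consistent": self.cpy_consistent,
            "notes": self.notes,
        }
        if config is not None:
            d["config"] = config.to_dict()
        return d


def _cpy_consistent(reading, sequence: str) -> bool:
    """Does the CPY C-terminal reading agree with a candidate sequence?"""
    for offset, cls in enumerate(reading.residues):
        if not cls:
            continue  # unexplained step: no evidence either way
        if offset >= len(sequence):
            return False
        res = sequence[len(sequence) - 1 - offset]
        il = {"I": "L", "L": "I"}.get(res)
        if res not in cls and (il is None or il not in cls):
            return False
    return True


def run_pipeline(
    isd: PeakList,
    native_mh: float,
    alkylated_mh: float,
    contigs: list[Contig],
    pmf: PeakList | None = None,
    msms: dict[float, PeakList] | None = None,
    cpy: list[PeakList] | None = None,
    config: RunConfig | None = None,
) -> EvidenceReport:
    """Run the complete inference chain on one peptide's observations."""
    cfg = config or RunConfig()
    notes = [
        "mature boundaries are delimited by intact-mass matching around the "
        "sequence tag; propeptide cleavage motifs are not modeled"
    ]

    # 1. de novo tag from the ISD ladder
    tags = read_isd_ladder(isd, cfg.ladder_tol)
    tags = [t for t in tags if len(t) >= 5]
    if not tags:
        return EvidenceReport(
            None, None, None, None, None, 0, 0, None, 0, 0, None, None,
            notes + ["no sequence tag of length >= 5 could be read"],
        )
    tag = tags[0]

    # 2. cysteine / disulfide count from the alkylation shift
    try:
        n_cys, n_ss = infer_cys_count(
            alkylated_mh - native_mh, CysState.OXIDIZED, tolerance=1.0
        )
    except ValueError as exc:
        n_cys, n_ss = 0, 0
        notes.append(str(exc))

    # 3. tag-bearing precursors in the transcriptome (all readable tags
    # contribute; a corrupted top tag must not mask a clean shorter one)
    orfs = extract_orfs(contigs, cfg.min_orf_aa)
    hits = []
    seen_loci: set[tuple[str, int, int]] = set()
    search_tags = []
    for t in tags:
        search_tags.append(t)
        # the gap-free runs of a corrupted read are searchable on their own
        search_tags.extend(s for s in t.segments() if len(s) < len(t))
    for t in search_tags:
        found = tag_search(t, orfs, cfg.max_mismatch)
        if not found and len(t) >= 12:
            # phantom ladder steps shift the register; retry allowing indels,
            # with a budget that grows with tag length
            found = tag_search_fuzzy(t, orfs, max_edits=max(2, len(t) // 8))
            if found:
                notes.append(
                    f"tag {t.as_string()} matched only under edit distance "
                    "(ladder read likely contains an insertion or deletion)"
                )
        for h in found:
            locus = (h.contig_id, h.frame, h.tag_start)
            if locus not in seen_loci:
                seen_loci.add(locus)
                hits.append(h)

    # 4. mature-peptide delimitation by intact mass; near-isobaric windows
    # (paralogs, shifted boundaries) are discriminated by the orthogonal
    # evidence: tryptic PMF agreement first, CPY consistency second
    cpy_reading = (
        interpret_cpy(cpy, cfg.cpy_tol, cys_addition=ETHANOLYL_ADDITION)
        if cpy else None
    )
    scored = []
    seen_cand: set[tuple[str, str]] = set()
    for hit in hits:
        hit = delimit_mature_by_mass(
            hit, native_mh, n_ss, tolerance=cfg.mature_mass_tol
        )
        for cand in hit.candidates[:5]:
            sequence = hit.protein[cand.sequence_slice]
            key = (sequence, cand.c_terminus.value)
            if key in seen_cand:
                continue
            seen_cand.add(key)
            alk = PeptideSpec(sequence, 0, CysState.ETHANOLYL, cand.c_terminus)
            n_matched = 0
            if pmf is not None and len(pmf):
                theo = [
                    f for f in tryptic_digest(alk, cfg.max_missed) if f.mh > 500.0
                ]
                n_matched = match_pmf(pmf, theo, cfg.pmf_tol).n_matched
            cpy_ok = (
                _cpy_consistent(cpy_reading, sequence) if cpy_reading else False
            )
            scored.append(
                (n_matched, cpy_ok, -abs(cand.residual), len(sequence), hit, cand)
            )
    if not scored:
        return EvidenceReport(
            None, n_ss, None, None, tag.as_string(), len(tag), len(hits),
            None, 0, 0, None, None,
            notes + ["no precursor window matched the observed intact mass"],
        )
    scored.sort(key=lambda t: t[:4], reverse=True)
    _, _, _, _, hit, cand = scored[0]
    sequence = hit.protein[cand.sequence_slice]

    # 5. amidation from the intact-mass deficit vs the free-acid prediction
    free_acid = PeptideSpec(
        sequence, n_ss, CysState.OXIDIZED, CTerminus.FREE_ACID
    )
    ami = detect_amidation(
        native_mh, mh_ion(peptide_mass(free_acid)),
        cfg.amide_window, cfg.free_acid_tol,
    )
    cterm = CTerminus.AMIDE if ami.verdict == "amide" else CTerminus.FREE_ACID

    # 6. tryptic PMF tally on the alkylated species of the chosen candidate
    alk = PeptideSpec(sequence, 0, CysState.ETHANOLYL, cterm)
    pmf_matched = pmf_total = 0
    if pmf is not None and len(pmf):
        theo = [f for f in tryptic_digest(alk, cfg.max_missed) if f.mh > 500.0]
        res = match_pmf(pmf, theo, cfg.pmf_tol)
        pmf_matched, pmf_total = res.n_matched, len(theo)

    # 7. MS/MS coverage of tryptic fragments
    coverage = None
    if msms:
        covs = []
        frags = {round(f.mh, 2): f for f in tryptic_digest(alk, 0)}
        for mh_key, peaks in msms.items():
            frag = frags.get(round(mh_key, 2))
            if frag is None:
                frag = min(frags.values(), key=lambda f: abs(f.mh - mh_key))
                if abs(frag.mh - mh_key) > cfg.pmf_tol:
                    continue
            covs.append(annotate_msms(frag.spec, peaks, cfg.msms_tol).coverage)
        coverage = sum(covs) / len(covs) if covs else None

    # 8. CPY C-terminal ladder reconciliation
    cpy_verdict = None
    cpy_ok = None
    if cpy_reading is not None:
        cpy_verdict = cpy_reading.verdict
        cpy_ok = _cpy_consistent(cpy_reading, sequence)

    return EvidenceReport(
        sequence=sequence,
        n_disulfides=n_ss,
        amidation_verdict=ami.verdict,
        cpy_verdict=cpy_verdict,
        tag=tag.as_string(),
        tag_length=len(tag),
        n_precursor_hits=len(hits),
        mass_residual=cand.residual,
        pmf_matched=pmf_matched,
        pmf_total_theoretical=pmf_total,
        msms_mean_coverage=coverage,
        cpy_consistent=cpy_ok,
        notes=notes,
    )
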