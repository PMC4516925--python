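"""Peak-list inference: ladder reading, PMF matching, amidation, CPY, MS/MS."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from venomseq.masses import (
    ETHANOLYL_ADDITION,
    RESIDUE_MASS,
    CTerminus,
    CysState,
    PeptideSpec,
    mh_ion,
    peptide_mass,
)
from venomseq.fragments import by_ion_series, c_ion_series, tryptic_digest
from venomseq.denovo import (
    PeakList,
    annotate_msms,
    detect_amidation,
    interpret_cpy,
    match_pmf,
    read_isd_ladder,
    substitution_from_delta,
)
from venomseq.simulate import gen_cpy_series

from _oracles import brute_force_substitutions

SEQ = st.text(alphabet=sorted(RESIDUE_MASS), min_size=4, max_size=25)


def full_ladder(seq, cterm=CTerminus.FREE_ACID):
    series = c_ion_series(PeptideSpec(seq, c_terminus=cterm), include_full=True)
    return PeakList.from_pairs(series.mz())


class TestLadderReading:
    def test_complete_noiseless_ladder_recovers_tag(self, tag13_sequence):
        tags = read_isd_ladder(full_ladder(tag13_sequence), 0.05)
        assert len(tags[0]) == 13
        assert tags[0].matches(tag13_sequence)

    def test_single_dropout_bridged_as_gap_pair(self, tag13_sequence):
        series = c_ion_series(PeptideSpec(tag13_sequence), include_full=True)
        mzs = [mz for i, mz in series.ions if i != 5]
        tags = read_isd_ladder(PeakList.from_pairs(mzs), 0.05)
        top = tags[0]
        assert len(top) == 13
        assert len(top.gap_steps) == 2  # one bridge = two gap positions
        assert top.matches(tag13_sequence)

    def test_two_peaks_isoleucine_leucine_class(self):
        tags = read_isd_ladder(PeakList.from_pairs([500.0, 613.084]), 0.05)
        assert [sorted(c) for c in tags[0].positions] == [["I", "L"]]

    def test_lys_gln_resolution_depends_on_tolerance(self):
        # K and Q differ by 0.0364 Da; only a tighter tolerance separates them
        peaks = PeakList.from_pairs([500.0, 500.0 + RESIDUE_MASS["K"]])
        coarse = read_isd_ladder(peaks, 0.05, infer_anchor_residue=False)
        fine = read_isd_ladder(peaks, 0.01, infer_anchor_residue=False)
        assert coarse[0].positions[0] == frozenset("KQ")
        assert fine[0].positions[0] == frozenset("K")

    def test_empty_peaklist(self):
        assert read_isd_ladder(PeakList.from_pairs([]), 0.3) == []

    @given(SEQ)
    def test_round_trip_up_to_il(self, seq):
        """Noiseless full ladders always read back to the true sequence."""
        tags = read_isd_ladder(full_ladder(seq), 0.02)
        assert tags[0].matches(seq)

    def test_tolerance_must_be_positive(self):
        with pytest.raises(ValueError):
            read_isd_ladder(PeakList.from_pairs([100.0]), 0.0)


class TestMatchPmf:
    def test_perfect_match(self):
        theo = tryptic_digest(PeptideSpec("ACKDEMRGGWK"), 1)
        obs = PeakList.from_pairs([f.mh for f in theo])
        res = match_pmf(obs, theo, 0.5)
        assert res.n_matched == len(obs)
        assert not res.unexplained
        assert all(abs(r) < 1e-9 for _, _, r in res.matches)

    def test_out_of_tolerance_peak_unexplained(self):
        theo = tryptic_digest(PeptideSpec("ACKDEMR"), 0)
        obs = PeakList.from_pairs([theo[0].mh + 0.6])
        res = match_pmf(obs, theo, 0.5)
        assert res.n_matched == 0
        assert len(res.unexplained) == 1

    def test_paralog_fingerprints_share_nonvariant_fragments(self):
        """Two 35-mers differing only at the last residue share every
        fragment that excludes that position."""
        base = "GACWDEKRMSTVYKAAGHNPKWQEFDSKGGILWEI"
        other = base[:-1] + "F"
        d1 = tryptic_digest(PeptideSpec(base), 0)
        d2 = tryptic_digest(PeptideSpec(other), 0)
        obs1 = PeakList.from_pairs([f.mh for f in d1 if f.end < 35])
        res = match_pmf(obs1, d2, 0.5)
        assert res.n_matched == len(obs1)
        assert all(abs(r) < 1e-9 for _, _, r in res.matches)


class TestAmidation:
    def test_printed_deficit_calls_amide(self):
        call = detect_amidation(4105.04, 4105.81)
        assert call.delta == pytest.approx(0.77, abs=1e-9)
        assert call.verdict == "amide"

    def test_one_da_deficit_calls_amide(self):
        assert detect_amidation(4137.72, 4138.76).verdict == "amide"

    def test_identical_masses_free_acid(self):
        assert detect_amidation(1000.0, 1000.0).verdict == "free_acid"

    def test_large_deficit_inconclusive(self):
        assert detect_amidation(1000.0, 1003.0).verdict == "inconclusive"

    @given(
        st.floats(min_value=-1.5, max_value=1.5),
        st.floats(min_value=100.0, max_value=5000.0),
    )
    def test_verdict_invariant_under_common_shift(self, delta, shift):
        base = 4000.0
        a = detect_amidation(base, base + delta)
        b = detect_amidation(base + shift, base + shift + delta)
        assert a.verdict == b.verdict


class TestSubstitution:
    def test_f18_f19_delta_contains_ile_phe(self):
        subs = substitution_from_delta(33.7, 0.5)
        assert ("I", "F") in subs and ("L", "F") in subs

    def test_zero_delta_empty(self):
        assert substitution_from_delta(0.0, 0.02) == set()

    def test_exact_ile_to_phe_at_tight_tolerance(self):
        delta = RESIDUE_MASS["F"] - RESIDUE_MASS["I"]
        assert substitution_from_delta(delta, 0.003) == {("I", "F"), ("L", "F")}

    @given(st.floats(min_value=-130.0, max_value=130.0))
    def test_agrees_with_exhaustive_scan(self, delta):
        assert substitution_from_delta(delta, 0.5) == brute_force_substitutions(
            delta, 0.5
        )


class TestInterpretCpy:
    def test_amidated_terminal_phe(self):
        parent = PeptideSpec("GASTKWHECF", c_terminus=CTerminus.AMIDE)
        series = gen_cpy_series(parent, mz_jitter_sd=0.0, seed=0)
        reading = interpret_cpy(series, 0.3)
        assert reading.verdict == "amide"
        assert reading.step_masses[0] == pytest.approx(146.084, abs=1e-3)
        assert "F" in reading.residues[0]

    def test_free_acid_terminal_phe(self):
        parent = PeptideSpec("GASTKWHECF")
        series = gen_cpy_series(parent, mz_jitter_sd=0.0, seed=0)
        reading = interpret_cpy(series, 0.3)
        assert reading.verdict == "free_acid"
        assert reading.step_masses[0] == pytest.approx(147.068, abs=1e-3)

    def test_alkylated_cys_step_needs_cys_addition(self):
        parent = PeptideSpec("GASTKWHECF", cys_state=CysState.ETHANOLYL)
        series = gen_cpy_series(parent, mz_jitter_sd=0.0, seed=0)
        reading = interpret_cpy(series, 0.3, cys_addition=ETHANOLYL_ADDITION)
        assert "C" in reading.residues[1]

    def test_static_series_reads_nothing(self):
        pl = PeakList.from_pairs([2000.0])
        reading = interpret_cpy([pl, pl, pl], 0.3)
        assert reading.residues == ()
        assert reading.verdict is None

    def test_reads_cterminal_sequence_inward(self):
        parent = PeptideSpec("GASTKWHEMF", c_terminus=CTerminus.AMIDE)
        series = gen_cpy_series(parent, mz_jitter_sd=0.0, seed=1)
        reading = interpret_cpy(series, 0.25)
        read = [
            "".join(sorted(c)) for c in reading.residues[:5]
        ]
        assert read[0] == "F"
        assert read[1] == "M"
        assert read[2] == "E"

    def test_needs_two_timepoints(self):
        with pytest.raises(ValueError):
            interpret_cpy([PeakList.from_pairs([100.0])], 0.3)


class TestAnnotateMsms:
    def test_full_theoretical_set_full_coverage(self):
        spec = PeptideSpec("GASTKWHE")
        b, y = by_ion_series(spec)
        peaks = PeakList.from_pairs(b.mz() + y.mz())
        assert annotate_msms(spec, peaks, 0.3).coverage == 1.0

    def test_empty_peaks_zero_coverage(self):
        spec = PeptideSpec("GASTKWHE")
        assert annotate_msms(spec, PeakList.from_pairs([]), 0.3).coverage == 0.0

    def test_cterminal_y_ions_cover_half(self):
        spec = PeptideSpec("GASTKWHEDV")  # 10 residues, 9 bonds
        _, y = by_ion_series(spec)
        half = [mz for j, mz in y.ions if j <= 5]
        cov = annotate_msms(spec, PeakList.from_pairs(half), 0.3).coverage
        assert abs(cov - 0.5) <= 1.5 / 9
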