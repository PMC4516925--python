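"""Synthetic-data generators with known ground truth.

Everything the inference pipeline consumes can be generated here: ISD c-ion
spectra with dropout/jitter/noise peaks, alkylated tryptic PMFs, MS/MS peak
sets, CPY time courses, a transcriptome with planted toxin precursors and
paralogs, and TEVC dose-response / I-V tables.  All randomness flows from
one explicit integer seed per generator call; generators never touch global
random state, so regeneration from (seed, parameters) is reproducible.

What is emulated — and what is not.  Spectra are peak lists: stick masses
with Gaussian m/z jitter (external-calibration error), independent peak
dropout and uniform chemical-noise peaks.  No isotope envelopes, intensity
physics, adducts or multiply charged species.  Transcriptome contigs are
uniform-random nucleotide background plus reverse-translated precursors on
random strands; no sequencing error or chimeras.  Pharmacology tables are
the Hill / Boltzmann-conductance models plus additive Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masses import (
    CTerminus,
    CysState,
    PeptideSpec,
    mh_ion,
    peptide_mass,
)
from .fragments import by_ion_series, c_ion_series, cpy_ladder, tryptic_digest
from .denovo import PeakList
from .transcriptome import Contig
from .pharm import boltzmann_current, hill_fraction

__all__ = [
    "GroundTruth",
    "gen_isd_spectrum",
    "gen_pmf_peaks",
    "gen_msms_peaks",
    "gen_cpy_series",
    "gen_transcriptome",
    "gen_tevc",
    "gen_iv",
    "random_ick_toxin",
    "build_precursor",
    "reverse_translate",
    "simulate_study",
]

# fixed arbitrary codon per residue (first codon alphabetically); codon
# realism is irrelevant to the searches being tested
_CODON = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGA", "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "AGC", "T": "ACA", "V": "GTA", "W": "TGG", "Y": "TAC",
}
_NON_CYS = "ADEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "AILVFM"


@dataclass
class GroundTruth:
    """Everything planted into a synthetic dataset, for later checking."""

    seed: int
    mature_sequence: str | None = None
    n_disulfides: int = 0
    amidated: bool = False
    precursor: str | None = None
    signal_len: int = 0
    pro_len: int = 0
    n_paralogs: int = 0
    ic50_nM: float | None = None
    nh: float | None = None
    v05_mV: float | None = None
    k_mV: float | None = None
    vrev_mV: float | None = None
    shift_mV: float | None = None
    gmax_scale: float | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def gen_isd_spectrum(
    spec: PeptideSpec,
    dropout_prob: float = 0.05,
    mz_jitter_sd: float = 0.02,
    n_noise_peaks: int = 5,
    seed: int = 0,
) -> PeakList:
    """Simulate the c-ion ladder an ISD spectrum of *spec* would show.

    The reductive matrix opens disulfides in source, so the ladder is
    generated from the reduced peptide regardless of the native state.
    Each c ion drops out independently with *dropout_prob*; surviving peaks
    get Gaussian m/z jitter; *n_noise_peaks* uniform random peaks are added
    across the ladder's m/z range.
    """
    if not 0 <= dropout_prob <= 1:
        raise ValueError("dropout_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    reduced = PeptideSpec(
        spec.sequence, 0, CysState.REDUCED, spec.c_terminus
    )
    series = c_ion_series(reduced)
    mzs = []
    for _, mz in series.ions:
        if rng.random() < dropout_prob:
            continue
        mzs.append((mz + rng.normal(0.0, mz_jitter_sd) if mz_jitter_sd else mz, 100.0))
    hi = series.ions[-1][1] + 50.0
    for _ in range(n_noise_peaks):
        mzs.append((float(rng.uniform(150.0, hi)), 5.0))
    if not mzs:
        return PeakList(np.empty(0), np.empty(0), "isd")
    return PeakList.from_pairs(mzs, source="isd")


def gen_pmf_peaks(
    spec: PeptideSpec,
    max_missed: int = 2,
    mz_jitter_sd: float = 0.02,
    dropout_prob: float = 0.0,
    seed: int = 0,
) -> PeakList:
    """Observed tryptic PMF of a peptide (typically the alkylated species)."""
    rng = np.random.default_rng(seed)
    frags = tryptic_digest(spec, max_missed=max_missed)
    mzs = [
        (f.mh + rng.normal(0.0, mz_jitter_sd), 50.0)
        for f in frags
        if rng.random() >= dropout_prob and f.mh > 500.0  # low-mass cutoff
    ]
    return PeakList.from_pairs(mzs, source="pmf")


def gen_msms_peaks(
    fragment_spec: PeptideSpec,
    mz_jitter_sd: float = 0.02,
    dropout_prob: float = 0.1,
    seed: int = 0,
) -> PeakList:
    """Observed b/y fragment peaks for one MS/MS-selected precursor."""
    rng = np.random.default_rng(seed)
    b, y = by_ion_series(fragment_spec)
    mzs = [
        (mz + rng.normal(0.0, mz_jitter_sd), 30.0)
        for _, mz in (*b.ions, *y.ions)
        if rng.random() >= dropout_prob
    ]
    return PeakList.from_pairs(mzs, source="msms")


def gen_cpy_series(
    spec: PeptideSpec,
    timepoints_min: tuple[float, ...] = (1, 2, 5, 10, 15, 30, 60),
    residues_per_30min: float = 4.5,
    mz_jitter_sd: float = 0.02,
    seed: int = 0,
) -> list[PeakList]:
    """CPY digestion time course as MALDI peak lists (M+H+ of each species).

    Digestion depth grows with time (~*residues_per_30min* removals per
    30 min, saturating one residue short of the full length); every aliquot
    still contains all earlier truncation species plus the parent.
    """
    rng = np.random.default_rng(seed)
    n = len(spec)
    ladder = cpy_ladder(spec, n - 1)
    parent_mh = mh_ion(peptide_mass(spec))
    series = []
    for t in timepoints_min:
        depth = min(n - 1, int(round(residues_per_30min * t / 30.0)) + 1)
        mzs = [(parent_mh + rng.normal(0.0, mz_jitter_sd), 80.0)]
        for k, neutral, _ in ladder[:depth]:
            mzs.append((mh_ion(neutral) + rng.normal(0.0, mz_jitter_sd), 60.0))
        series.append(PeakList.from_pairs(mzs, source=f"cpy_t{t}"))
    return series


def random_ick_toxin(
    rng: np.random.Generator,
    length: int = 35,
    n_disulfides: int = 3,
    amidated: bool = True,
) -> PeptideSpec:
    """A random toxin-like peptide with the C-C-CC-C-C cysteine framework."""
    if length < 25:
        raise ValueError("ICK-like peptides need at least 25 residues")
    n_loop = length - 6
    # inter-cysteine segment lengths: s0 | C s1 C s2 CC s3 C s4 C | tail
    while True:
        s0 = int(rng.integers(1, 4))
        s1 = int(rng.integers(3, 7))
        s2 = int(rng.integers(3, 7))
        s3 = int(rng.integers(3, 7))
        s4 = int(rng.integers(3, 9))
        tail = n_loop - (s0 + s1 + s2 + s3 + s4)
        if 3 <= tail <= 12:
            break
    body = rng.choice(list(_NON_CYS), size=n_loop)
    it = iter(body)
    take = lambda n: "".join(next(it) for _ in range(n))
    seq = (
        take(s0) + "C" + take(s1) + "C" + take(s2) + "CC"
        + take(s3) + "C" + take(s4) + "C" + take(tail)
    )
    cterm = CTerminus.AMIDE if amidated else CTerminus.FREE_ACID
    return PeptideSpec(seq, n_disulfides, CysState.OXIDIZED, cterm)


def build_precursor(
    mature: PeptideSpec,
    rng: np.random.Generator,
    signal_len: int = 21,
    pro_len: int = 16,
) -> tuple[str, int, int]:
    """Signal peptide + propeptide + mature (+ Gly amidation donor).

    Returns (precursor protein, signal length, pro length).  The signal
    region is Met followed by hydrophobic residues; the propeptide is
    acidic-leaning and ends in Arg, mimicking typical toxin precursor
    processing sites without modelling them.
    """
    signal = "M" + "".join(rng.choice(list(_HYDROPHOBIC), size=signal_len - 1))
    pro = "".join(rng.choice(list("ADEGNQSTE"), size=pro_len - 1)) + "R"
    tail = "G" if mature.c_terminus is CTerminus.AMIDE else ""
    return signal + pro + mature.sequence + tail, signal_len, pro_len


def reverse_translate(protein: str) -> str:
    """Fixed-codon reverse translation (stop codon appended)."""
    return "".join(_CODON[a] for a in protein) + "TAA"


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def gen_transcriptome(
    n_background_contigs: int,
    planted_precursors: list[str],
    seed: int = 0,
    contig_len: tuple[int, int] = (300, 600),
    utr_len: tuple[int, int] = (30, 90),
) -> list[Contig]:
    """Background contigs plus planted precursor-bearing contigs.

    Each precursor protein is reverse-translated, framed by an in-frame
    upstream stop plus random UTRs, placed on a random strand, and shuffled
    into the contig list deterministically per seed.
    """
    if not planted_precursors:
        raise ValueError("need at least one planted precursor")
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    for i in range(n_background_contigs):
        n = int(rng.integers(contig_len[0], contig_len[1] + 1))
        contigs.append(Contig(f"bg{i:05d}", _random_nt(rng, n)))
    for i, prot in enumerate(planted_precursors):
        cds = reverse_translate(prot)
        up = _random_nt(rng, int(rng.integers(*utr_len))) + "TAA"
        down = _random_nt(rng, int(rng.integers(*utr_len)))
        nt = up + cds + down
        if rng.random() < 0.5:
            from Bio.Seq import Seq
            nt = str(Seq(nt).reverse_complement())
        contigs.append(Contig(f"tox{i:03d}", nt))
    order = rng.permutation(len(contigs))
    return [contigs[j] for j in order]


def _paralogs(
    mature: PeptideSpec,
    tag_span: tuple[int, int],
    n: int,
    rng: np.random.Generator,
) -> list[PeptideSpec]:
    """Paralogous matures sharing the tag region, varied outside it."""
    out = []
    lo, hi = tag_span  # 1-based inclusive, kept intact
    editable = [
        i for i in range(len(mature))
        if not (lo - 1 <= i <= hi - 1) and mature.sequence[i] != "C"
    ]
    for _ in range(n):
        seq = list(mature.sequence)
        k = int(rng.integers(1, 4))
        for i in rng.choice(editable, size=min(k, len(editable)), replace=False):
            seq[i] = str(rng.choice(list(_NON_CYS)))
        out.append(mature.replace(sequence="".join(seq)))
    return out


def gen_tevc(
    ic50: float,
    nh: float,
    concentrations=(30.0, 100.0, 300.0, 1000.0, 3000.0),
    n_reps: int = 6,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic concentration-inhibition table from the Hill model."""
    if ic50 <= 0 or nh <= 0:
        raise ValueError("ic50 and nh must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        for c in concentrations:
            f = hill_fraction(c, ic50, nh) + rng.normal(0.0, noise_sd)
            rows.append((float(c), float(f), rep))
    return pd.DataFrame(rows, columns=["conc_nM", "fraction", "replicate"])


def gen_iv(
    v05: float = -18.0,
    k: float = 4.5,
    vrev: float = 65.0,
    gmax: float = 1.0,
    shift_mV: float = 0.0,
    scale: float = 1.0,
    grid=tuple(range(-60, 71, 10)),
    noise_sd: float = 0.02,
    n_reps: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic peak-current I-V family (control and optional peptide rows).

    Noise is additive Gaussian on the conductance scale with SD
    *noise_sd* × Gmax; the peptide condition applies (*shift_mV*, *scale*)
    to (V0.5, Gmax).  When shift and scale leave the model unchanged the
    peptide condition is omitted.
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    conditions = [("control", v05, gmax)]
    if shift_mV != 0.0 or scale != 1.0:
        conditions.append(("peptide", v05 + shift_mV, gmax * scale))
    rows = []
    for cond, v05_c, gmax_c in conditions:
        for rep in range(n_reps):
            g = gmax_c / (1.0 + np.exp((v05_c - grid) / k))
            g = g + rng.normal(0.0, noise_sd * gmax, size=grid.size)
            i = g * (grid - vrev)
            rows.extend(
                (float(v), float(cur), cond, rep) for v, cur in zip(grid, i)
            )
    return pd.DataFrame(rows, columns=["potential_mV", "current", "condition", "replicate"])


def simulate_study(
    seed: int,
    length: int = 35,
    n_disulfides: int = 3,
    amidated: bool = True,
    n_paralogs: int = 10,
    n_background_contigs: int = 50,
    tag_len: int = 13,
    mz_jitter_sd: float = 0.02,
    dropout_prob: float = 0.05,
) -> dict:
    """Generate one complete synthetic sequencing case.

    Returns a dict with the planted peptide, the observed native and
    alkylated intact M+H+, the ISD spectrum, the alkylated tryptic PMF and
    per-fragment MS/MS peaks, the CPY series (on the alkylated peptide) and
    a transcriptome whose planted contigs include the true precursor plus
    *n_paralogs* tag-sharing paralogs — together with the GroundTruth.
    """
    rng = np.random.default_rng(seed)
    mature = random_ick_toxin(rng, length, n_disulfides, amidated)
    alkylated = PeptideSpec(
        mature.sequence, 0, CysState.ETHANOLYL, mature.c_terminus
    )
    native_mh = mh_ion(peptide_mass(mature)) + rng.normal(0.0, mz_jitter_sd)
    alk_mh = mh_ion(peptide_mass(alkylated)) + rng.normal(0.0, mz_jitter_sd)

    isd = gen_isd_spectrum(
        mature, dropout_prob, mz_jitter_sd,
        n_noise_peaks=5, seed=int(rng.integers(2**31)),
    )
    pmf = gen_pmf_peaks(
        alkylated, mz_jitter_sd=mz_jitter_sd, seed=int(rng.integers(2**31))
    )
    frags = [f for f in tryptic_digest(alkylated, 0) if len(f.spec) >= 5]
    msms = {
        f.mh: gen_msms_peaks(f.spec, mz_jitter_sd, seed=int(rng.integers(2**31)))
        for f in frags
    }
    cpy = gen_cpy_series(
        alkylated, mz_jitter_sd=mz_jitter_sd, seed=int(rng.integers(2**31))
    )

    precursor, slen, plen = build_precursor(mature, rng)
    paralog_specs = _paralogs(mature, (1, tag_len), n_paralogs, rng)
    paralog_precursors = [build_precursor(p, rng)[0] for p in paralog_specs]
    contigs = gen_transcriptome(
        n_background_contigs,
        [precursor] + paralog_precursors,
        seed=int(rng.integers(2**31)),
    )
    truth = GroundTruth(
        seed=seed,
        mature_sequence=mature.sequence,
        n_disulfides=n_disulfides,
        amidated=amidated,
        precursor=precursor,
        signal_len=slen,
        pro_len=plen,
        n_paralogs=n_paralogs,
    )
    return {
        "mature": mature,
        "alkylated": alkylated,
        "native_mh": float(native_mh),
        "alkylated_mh": float(alk_mh),
        "isd": isd,
        "pmf": pmf,
        "msms": msms,
        "cpy": cpy,
        "contigs": contigs,
        "truth": truth,
    }
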