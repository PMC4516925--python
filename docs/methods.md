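# Methods

`venomseq` models the proteomic and electrophysiological workflow used to
characterise disulfide-rich spider-venom peptides that inhibit voltage-gated
sodium (NaV) channels: mature-peptide sequence inference from MALDI-TOF peak
lists plus a venom-gland transcriptome, and Hill/Boltzmann analysis of
two-electrode voltage-clamp (TEVC) data.  This note records the models, the
parameters that matter, the synthetic-data conditions, and the design choices
made where the design was genuinely open.

## Mass model

All masses are monoisotopic daltons.  A peptide's neutral mass is

    M = Σ residue masses + H2O
        + n_SS · (−2.015650)                  (per disulfide, vs reduced)
        + n_Cys · (+44.026215)                (per ethanolyl cap, if alkylated)
        + (−0.984016)                         (if C-terminally amidated)

with singly protonated ions at M + 1.007276.  The 20-residue table is
hard-coded from standard atomic compositions (and cross-checked against
pyteomics in the test suite) so mass arithmetic is hermetic and immutable.
Measured from the native (oxidised) peptide, reduction-plus-ethanolylation
adds 45.034 Da per cysteine — six cysteines give the diagnostic ~270 Da
shift from which the cysteine and disulfide count is inferred by integer
search (tolerance 1 Da by default).  Average masses, charge states above
1+, and isotope envelopes are out of scope: the workflow reads
reflector-mode monoisotopic M+H+ peak lists only.

## Fragment models

* **ISD c ions.** In-source decay with a reductive matrix yields a dominant
  c-ion series; c_i = Σ(residues 1..i) + NH3 + H+.  Consecutive c ions
  differ by one residue mass, so ladders read directly as sequence.
  Disulfides are treated as opened (the matrix reduces them in source).
* **Tryptic digest.** Cleavage after Lys/Arg except before Pro; all
  fragments with up to `max_missed` (default 2) internal missed cleavages
  are generated.  Only the C-terminal fragment inherits the parent's
  amidation.  Zero-missed fragments tile the parent exactly, and their
  masses sum to parent + (n−1)·H2O — both are enforced as invariants.
* **b/y MS/MS ions.** b_i = prefix + H+; y_j = suffix + H2O + H+ (+ amide
  offset when the parent is amidated).  The complementarity identity
  b_i + y_{n−i} = MH+ + H+ holds exactly and is property-tested.
* **CPY ladders.** Carboxypeptidase Y removes one C-terminal residue at a
  time; the step-1 removed mass carries the amide offset when the parent is
  amidated (an amidated terminal residue reads ~1 Da light — the decisive
  amidation evidence).  All truncation products are free acids.

## Inference

* **Ladder reading** builds a DAG over peaks: an edge joins peaks whose m/z
  difference matches a residue mass within the ladder tolerance (default
  0.3 Da).  A single dropped peak is bridged by a two-residue composite
  step, reported as a flagged gap pair carrying the union of candidate
  residues; larger gaps split the tag.  Maximal paths are peeled off by
  dynamic programming, scoring first the number of residue positions, then
  fewer gaps.  Ile/Leu always collapse into one class; Lys/Gln separate
  only below their 0.0364 Da mass difference.  The first peak of a path is
  additionally interpreted as a c1 ion, which when it matches a residue
  contributes the N-terminal position.  A small-peak-list brute-force path
  enumerator in the test suite certifies that the DP attains the optimal
  score.
* **PMF matching** is greedy nearest-mass one-to-one assignment (default
  0.5 Da), ties broken toward the smaller residual and then the lower-mass
  fragment; combinatorial assignment buys nothing at these list sizes.
* **Amidation calls** use the deficit δ = predicted free-acid MH+ −
  observed MH+: amide for δ in [0.6, 1.3] Da (centred near 0.984 with
  calibration slack), free acid for |δ| ≤ 0.3 Da, else inconclusive.  The
  windows are configurable; the defaults accommodate the ~0.8–1.0 Da
  deficits typical of externally calibrated MALDI-TOF data.
* **CPY interpretation** pools truncation masses across all time points
  (the ladder accumulates), merges near-duplicates (0.25 Da), reads
  descending consecutive differences as removed residues, and matches the
  terminal step under both plain and amidated hypotheses.  On alkylated
  peptides the cysteine entry is shifted by +44.026 Da — capped Cys is then
  nearly isobaric with Phe, a real ambiguity the reader reports as a class.
* **Transcriptome mining** replaces BLAST with exact ambiguity-aware
  subsequence search over six-frame stop-to-stop ORFs (≥ 30 aa, Met-trimmed
  variants retained): tags are short, the database is small, and exact
  search is deterministic with no external binary.  Up to one mismatch is
  allowed; when a corrupted read (a phantom residue from a chemical-noise
  peak splitting a ladder step) defeats mismatch-only search, a fallback
  Levenshtein search (edlib) with a budget of tag-length/8 edits absorbs
  the register shift, and the gap-free runs of the tag are also searched
  independently.
* **Mature-peptide delimitation** slides candidate boundaries around the
  tag (30 residues upstream of the tag start, 3 of slack past it for a
  spuriously prepended position, 40 downstream of the tag end — covering
  the 29–41-residue range of the relevant toxin families) and keeps
  windows whose oxidised theoretical M+H+ matches the observed intact mass
  within 0.25 Da under either C-terminus hypothesis.  Candidates rank by
  absolute residual, then longer window, then proximity of the window
  start to the tag start (ISD ladders anchor at the mature N terminus;
  this resolves exact-tie isobars such as a window shifted across
  identical flanking residues).  Propeptide cleavage motifs are
  deliberately not modelled — the intact mass is the decisive evidence —
  and reports say so.
* **Evidence reconciliation.** The pipeline scores surviving candidates by
  tryptic-PMF agreement first and CPY consistency second before the mass
  residual: near-isobaric alternatives (e.g. a paralog window extended by
  its Gly amidation donor, or Glu-amide vs Gln) are separated only by this
  orthogonal evidence, exactly as in manual practice.

## Family assignment

The cysteine framework is derived positionally (adjacent cysteines
collapse to "CC"); the ICK flag requires exactly six cysteines in
C-C-CC-C-C.  Pairwise identity uses a global alignment with match +1,
mismatch 0, linear gap −1, and counts matches over all alignment columns
including gaps — the denominator convention is recorded in output metadata
since published identity figures rarely state theirs.  Family assignment
is nearest-reference; the bundled reference FASTA contains synthetic
placeholder sequences (random ICK-framework peptides at family-typical
lengths) so the machinery is exercisable without shipping curated data;
real classification requires user-supplied references.

## Pharmacology

Concentration-inhibition data are fit with the Hill equation
f(c) = 1 / (1 + (c/IC50)^nH), top and bottom fixed at 1 and 0 (fraction-of-
control data under full block; free asymptotes are opt-in).  I-V families
are fit with the Boltzmann-conductance model
I(V) = Gmax·(V − Vrev) / (1 + exp((V0.5 − V)/k)); an equivalent
conductance-transform route (G = I/(V − Vrev) on V < Vrev, logistic fit)
is provided and agrees with the direct fit on noiseless data.  Vrev is
fixed at +65 mV by default (configurable, reported in output), not fitted.
All fits are Levenberg-Marquardt least squares (lmfit) with multi-start
initialisation — five log-spaced IC50 starts spanning the tested
concentrations, V0.5 starts at grid quartiles — and 1e−8 convergence
tolerances.  Gating shifts are ΔV0.5 = V0.5(peptide) − V0.5(control),
positive depolarising; voltage-dependence of inhibition is
1 − I_pep/I_ctrl on potentials where the control magnitude exceeds 5% of
its maximum (the ratio is unstable near reversal).

## Synthetic-data conditions

Generators take one explicit integer seed each and never touch global
random state.  Defaults represent a plausibly realistic MALDI-TOF/TEVC
study and are fixed:

| parameter | default | rationale |
|---|---|---|
| m/z jitter SD | 0.02 Da | external-calibration residuals of ~0.1–0.2 Da at 4 kDa scale |
| c-ion dropout | 0.05 | occasional missing ladder peaks |
| noise peaks per ISD spectrum | 5 | sparse chemical noise |
| dose-response noise SD | 0.03 (fraction) | replicate scatter of oocyte recordings |
| concentrations | 30–3000 nM, 6 replicates | brackets the ~200–500 nM potencies studied |
| I-V grid | −60..+70 mV, 10 mV steps, 6 replicates | the standard activation protocol |
| I-V noise | SD 2% of Gmax, on the conductance scale | keeps V0.5 recovery within ±1.5 mV |
| Boltzmann slope k (simulation) | 4.5 mV | places the peak inward current at −5.9 mV, inside the −10..−5 mV window observed for NaV1.7 activation with V0.5 = −18 mV and Vrev = +65 mV; k = 6 would push the peak to −3.9 mV, outside it |
| transcriptome | 50 background contigs (300–600 nt) + true precursor + 10 tag-sharing paralogs | mirrors a tag matching ~11 paralogous transcripts in a real venom-gland assembly |

Reverse translation uses a fixed arbitrary codon per residue — codon usage
is irrelevant to the searches being tested.  What the generators do *not*
emulate: isotope envelopes, intensity physics, adducts, multiply charged
ions, sequencing error, chimeric contigs, washout kinetics, leak currents.
Passing round-trip tests therefore demonstrates correctness of the
inference logic under calibration error, dropout and sparse noise — not
robustness to every artefact of real spectra.

## Problem sizes

The headline round trip runs 100 independent seeds (35-residue amidated
3-disulfide peptides, full observation sets, 61-contig transcriptomes) and
requires ≥ 99 full recoveries (sequence up to Ile/Leu, disulfide count,
amidation verdict).  Hill-recovery studies use 120–300 simulated datasets;
Boltzmann-recovery checks 60 noisy families.  These sizes give stable
pass/fail behaviour while keeping the full suite around a minute.

## Known limitations

* Ladder reading is path-based tag extraction, not full probabilistic
  de novo sequencing; intensities are ignored except implicitly through
  peak presence.
* Amidation windows are calibrated judgment, not a statistical model of
  mass error; borderline deficits (~0.3–0.6 Da) return "inconclusive".
* Delimitation assumes the intact observed mass belongs to a contiguous
  precursor window; truncated or post-translationally modified matures
  other than amidation are not represented.
* Identity percentages depend on the declared denominator convention and
  are not comparable across conventions.
* The Hill fit assumes complete block at saturation; partial blockers need
  the free-asymptote flag.
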