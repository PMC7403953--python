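# Methods

## The system and the reasoning being implemented

Thiamine diphosphate (ThDP, C12H19N4O7P2S, monoisotopic 425.045 Da in its
intrinsic thiazolium form) is the cofactor of transketolase. In the
one-substrate reaction the donor ketose (here hydroxypyruvate, whose
decarboxylation makes the reaction irreversible) is cleaved at the
cofactor, leaving a two-carbon "active glycolaldehyde" residue
(GliA, C2H4O2 as a composition delta, 60.0211 Da) covalently bound. Two
such residues condense to erythrulose. The package encodes the three
mass-spectrometric arguments that locate the GliA binding sites:

1. **Exact-mass assignment.** Protein-free supernatants show 1+ ions whose
   neutral masses equal ThDP plus adduct deltas: 485.066 (ThDP+GliA),
   483.050 (dehydro), 467.056/449.045 (−H2O/−2H2O cyclization products),
   and — only with the NaCNBH3 reductive trap — 487.082 (+2H), the
   signature of a labile (Schiff-base) linkage rendered stable by
   reduction.
2. **CID fragmentation.** Fragments of these precursors are explained by
   neutral losses (H2O 18.0106, HPO3 79.9663, H2P2O6 159.9327, O, H2,
   GliA) and by scission between the aminopyrimidine and thiazole rings.
   Fragments retaining GliA (e.g. 180.077 = aminopyrimidine 122.072 +
   GliA − H2; 164.082 = its deoxo form; 182.093 = its trapped dihydride)
   appear only for intermediates, never for bare ThDP — which places GliA
   on the aminopyrimidine amino group in addition to the canonical
   thiazole C2.
3. **Stoichiometry.** Erythrulose formed equals half the consumed
   substrate (96% and 92% of expectation at 1.0 and 0.5 mM loads),
   consistent with the first GliA remaining enzyme-bound.

## Mass conventions

* **Neutral-atom sums, no electron correction.** All reference masses for
  this system are printed as neutral-atom sums even for cationic species
  (425.045, not the 425.044 cation mass); the engine follows that
  convention throughout. At the 3-decimal working precision the electron
  mass (0.00055 Da) is at the edge of visibility and applying it would
  break agreement with every printed value.
* **Atomic masses** are the standard monoisotopic values bundled as an
  editable TSV (H 1.007825032, C 12, N 14.003074005, O 15.994914620,
  P 30.973761998, S 31.972071174). Unit tests cross-check sums against an
  independently maintained library (pyteomics).
* **Rounding** is decimal half-up (3 decimals for table-style masses,
  4 for component sums); Python's banker's rounding would differ visibly
  (e.g. 224.0145).
* **Two verification modes.** Printed identities are stated on
  pre-rounded components (60.0211 + 425.0449 = 485.0660, where full
  precision gives 485.06611). `tkms.identities` evaluates every identity
  both ways and reports them separately. Four identities disagree with
  their own printed result by one unit in the last digit
  (the 467.0557 dehydrogenation/deoxygenation identity, the
  observed-mass pair sum 180.076 + 303.981 − 1.008, and both tetrose
  recipes); they are reported as discrepancies, never reconciled.

## Candidate catalog

Generated by breadth-first application of signed composition deltas to
ThDP: +GliA (≤2), +H2 / −H2 (≤1), −H2O (≤2), plus a one-step
erythrulose-residue (+C4H6O3) alternative that is composition-identical to
+2GliA−H2O. Deduplication is by composition with shortest-provenance
preference; total GliA-equivalents are capped at two (the chemistry under
study involves at most two transferred residues). Roles follow the
provenance signature (cofactor / intermediate / trapped / dehydrated /
tetrose adduct). The result is 30 species, minimum mass separation ≈3700
ppm, so 5-ppm assignment is never ambiguous within the catalog. Known
control-spectrum contaminants (484.867, 486.961) are mass-only entries:
matching them flags a peak, it never assigns a composition.

## Assignment and trap detection

* MS1 tolerance default **5 ppm** (the instrument's stated accuracy figure;
  a prominent knob since that statement is ambiguous about direction).
* Ambiguity margin **0.5 ppm**: two in-tolerance candidates closer than
  this in |ppm| are reported as ambiguous rather than crowning an
  arbitrary winner below realistic calibration stability.
* Contaminant window **0.01 Da absolute**, not ppm — control-spectrum
  artifacts have unknown composition, so there is no theoretical mass to
  scale by. Peaks are flagged, never deleted.
* Trap pairs: a peak m in the no-reductant condition pairs with m + 2.01565
  in the with-reductant condition (window ppm-scaled); pairs whose heavy
  partner also occurs without reductant are segregated as not
  trap-specific.

## Fragment annotation

* **Loss paths**: all loss multisets to depth 3; a fragment takes the
  shortest in-tolerance path, ties broken by lexicographic loss-name
  order. Mass-equivalent readings collapse (−H2−O ≡ −H2O; 2×HPO3 ≡
  H2P2O6): path identities are composition-level, so precursor − Σlosses
  equals the fragment composition exactly by construction.
* **Subformula enumeration** (fallback, and the per-cell oracle for the
  report): exhaustive DFS over the sublattice of the precursor composition
  with mass-window pruning, ranked by |ppm|. A plausibility profile
  filters compositions no fragment of this molecule could have:
  H/C ≤ 3.1; ring-plus-double-bond equivalents in [−1, 9] (half-integers
  allowed for open-shell cations; 9 accommodates the doubly dehydrated
  species at RDBE 8.5); O ≥ 3·P (phosphorus occurs only as
  (di)phosphate); S ⇒ N ≥ 1 (sulfur occurs only in the thiazole ring).
  All 34 printed fragment compositions pass the profile. An unconstrained
  profile exists for oracle comparisons. MS/MS tolerance default **10 ppm**
  (CID spectra are less well calibrated than MS1).
* **Complementary pairs**: for fragments a, b, restored-loss subsets of
  {H2O, HPO3} and hydrogen transfer n ∈ [−2, +2], report pairs with
  |a + b + restored − M − n·1.00783| ≤ 0.01 Da. The slack bound of ±2
  covers the observed ±1.008 transfers and the 2.015 trap shift; at the
  0.01 Da window the (n, restored) explanation per pair is unique because
  alternatives differ by ≥1 Da.
* **GliA flags**: a fragment matching the bare-ThDP control (or the
  control + 2.016, a trap-shifted cofactor fragment) within 0.01 Da is
  GliA-free; otherwise it is GliA-containing if subtracting some GliA
  remnant (C2H4O2, ±H2, −H2O, −O variants) leaves a sub-composition of
  ThDP; otherwise undetermined. On the transcribed 485-precursor fragment
  list this reproduces the reference table's asterisk column exactly.
* The 182.093 row of the reference table is printed with formula
  C8O2H10N3, whose mass is 180.077; the implementation assigns C8H12N3O2
  (= 182.093) and carries the printed string with a suspected-typo note.
  The unlabeled 140.081 mass (appearing only via 122.071 = 140.081 −
  18.010) enumerates to C6H10N3O and is kept in the identity list.

## Synthetic data

The simulator emulates the study's acquisition structure, not its physics:
centroided stick spectra, z = 1+ only, no isotope envelopes, profiles or
chromatography, and no intensity model beyond log-uniform draws over three
decades (figure intensities are out of scope). Defaults are the study
conditions: calibration noise σ = 1.5 ppm multiplicative (FT behavior),
scan range 200–1000 Da, contaminants drawn uniformly and copied into the
control within ±0.005 Da, trap condition adding +2.01565 partners for
GliA-containing species. MS/MS generation applies the loss grammar
(compositionally independent subset H2O/HPO3/GliA, depth ≤3) and emits
both members of each ring-scission split with a ±1 H transfer. Passing
recovery tests on these spectra therefore demonstrates the matching logic
(windows, flags, tie rules) under calibrated noise — not robustness to
peak-shape, isotope or intensity artifacts of real data.

Recovery benchmark (200 seeded replicates, 9 planted species, 1 shared
contaminant, 5 ppm tolerance): 100% at σ = 0, 99.9% at σ = 1.5 ppm, ~67%
at σ = 5, ~18% at σ = 20 — monotone degradation as noise passes the
matching tolerance, as expected for a |ppm| window of 3.3σ, 1σ, 0.25σ.

## Numerical and degenerate-input choices

* Rounded-component arithmetic uses decimal strings end-to-end (no binary
  float dust can flip a printed last digit).
* Peak lists sort ascending on construction; empty text spectra are
  errors, but an empty PeakList object is legal (an empty report section,
  not a crash). Subtraction driving an element negative raises naming the
  element; an adduct rule doing so silently prunes that branch.
* Assignment, annotation, pair-finding and report rendering are
  deterministic: fixed sort keys everywhere, byte-identical reports on
  identical inputs.
* Replicate seeds derive affinely from the master seed and stay below
  2^31.

## Problem sizes

The default test and analysis runs use the full 30-species catalog, the 58
transcribed fragment observations, and 200 simulation replicates per
recovery point; the complete suite runs in a few seconds on one CPU. These
sizes were chosen as the natural size of the system under study — the
catalogs and tables are the complete published ones, not samples.

## Known limitations

* Formula-level only: no bond-level structure elucidation, collision-energy
  or intensity modeling; the tricyclic-intermediate hypothesis is context,
  not computation.
* Charge fixed at 1+; no deconvolution, isotope scoring or average masses.
* The plausibility profile is tuned to thiamine chemistry; for other
  precursor classes its phosphate/sulfur rules should be revisited (they
  are parameters, not constants).
* At ±2–5 ppm observed error some low-mass compositions remain genuinely
  isobaric (e.g. 266.024: C8H13NO5PS vs C6H11N4O4PS); the report lists
  such alternatives rather than forcing a unique answer.
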