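# Methods

This note documents the models, conventions and design choices behind
`nitroscope`: what each stage computes, which parameters matter, what the
simulator does and does not emulate, and the numerical decisions that an
independent reimplementation would need to reproduce the outputs.

## Mass arithmetic

All masses are monoisotopic and kept at full floating-point precision
internally; the conventional 3-decimal presentation of modification deltas
is applied only at display/comparison time, because peak matching at
0.01 Da cannot absorb accumulated rounding error. Constants: proton
(charge carrier) 1.007276 Da, water 18.010565 Da; residue and atomic
masses come from pyteomics' NIST tables.

The default modification set is the standard nitrotyrosine search space:

| name              | formula     | delta (Da) | targets       | kind     |
|-------------------|-------------|-----------:|---------------|----------|
| nitroY            | +N +2O −H   | +44.985    | Y             | variable |
| oxidation         | +O          | +15.995    | M             | variable |
| acetyl            | +C2H2O      | +42.011    | protein N-term| variable |
| carbamidomethyl   | +C2H3NO     | +57.021    | C             | fixed    |

Custom sets load from YAML (`name`, `targets`, `formula` or `delta_mass`).
A peptidoform carries at most one modification per residue position;
"N-terminal nitroY" means a nitroY at peptide position 1. Fragmentation
generates the b and y series only (HCD-style), b1..b(n−1)/y1..y(n−1) at
charges up to a configurable maximum; a fragment carries exactly the
modifications localized within it, so b/y shift patterns localize a
modification. Complementarity — neutral(b_k) + neutral(y_{n−k}) = neutral
peptidoform mass — holds to 1e−9 Da by construction and is property-tested.
Average masses, isotope envelopes, neutral losses (including the
nitroTyr-characteristic O/NO losses) and internal fragments are out of
scope.

## Spectral comparison

The comparison pipeline is `normalize_and_filter → match_peaks →
cosine_similarity`, applied symmetrically to both spectra:

- **Normalization/filtering.** Intensities are rescaled to base peak = 100
  and peaks *strictly above* 2% of the base peak are retained ("over 2%"
  read as strict; a peak at exactly 2.0% is removed). Cosine is
  scale-invariant, so normalization does not change the score; it makes the
  filter well defined across acquisitions. Intensities enter the cosine
  untransformed (no square-root weighting).
- **Matching.** One-to-one peak matching at a 0.01 Da tolerance, greedy by
  ascending |Δm/z|, ties broken by lower m/z. Unmatched peaks enter the
  aligned vectors as (u_i, 0) or (0, v_i) slots, so spectrum-specific peaks
  penalize the score through the norms. Duplicate m/z values within one
  spectrum are merged by intensity summation on read so one-to-one matching
  is well defined.
- **Score.** cos θ = Σu_i v_i / √(Σu_i² · Σv_i²); defined as 0 when no
  peaks match; a pair passes when score > 0.7 (strict).

Greedy matching versus the exhaustive optimum (Hungarian assignment,
maximize matches then minimize total |Δm/z|): for fragment spectra of the
kind actually compared here — peak spacings far larger than twice the
tolerance, m/z jitter well inside it — the two coincide; the acceptance
suite verifies agreement on 1,000 simulated pairs. Under adversarially
clustered peaks (several peaks within one tolerance window) greedy can
drop a match the optimum keeps, and scores can then diverge; a property
test pins the guaranteed direction (greedy never exceeds the optimal match
count). Greedy is kept because it is deterministic, simple to specify, and
exact in the operating regime.

Fragment annotation labels each peak with the closest theoretical b/y ion
within 0.01 Da (ties: smaller |Δm/z|, then lower charge, then y over b).
Precursor m/z agreement is *not* enforced before comparison — pairs are
given explicitly by the pair table; an upstream precursor filter would be
a trivial addition.

## Catalog analyses

- **Counting unit.** A "peptide" is a distinct modified peptidoform (the
  sequence plus its set of nitroY positions), ignoring charge and
  replicate; a "protein" is the reported accession (no parsimony or
  shared-peptide reassignment — input tables carry one accession per PSM).
- **Site mapping.** protein_position = peptide_start + peptide_position − 1
  (both 1-based); with a FASTA available, any site whose protein residue is
  not tyrosine is rejected with a row-numbered diagnostic, and parsing
  stays total (valid + rejected = input rows), which the run report
  reconciles per stage.
- **N-terminal fractions** are computed over distinct peptidoforms per
  antibody × enrichment mode (not over PSMs): the fraction with nitroY at
  peptide position 1.
- **Overlap.** Exclusive Venn-region counts and plain subset intersections
  over every antibody subset, for proteins or peptidoforms, optionally per
  mode. Exclusive regions partition the union, giving an exact
  inclusion–exclusion consistency check.
- **Motif matrices.** Windows of half-width k = 7 (15-mers, configurable)
  are cut from the *protein* sequence around each distinct nitrated Y and
  padded with a terminal-gap symbol past protein ends. Columns report
  counts, frequencies (gaps included; columns sum to the window count) and
  log2-odds against the background; odds are conditional on observing a
  residue (gap cells excluded) and use the residue frequencies of the
  supplied FASTA as background — the proteome, not the identified peptides,
  to avoid circularity. A delta-method standard error per log-odds cell is
  provided for significance screening.

## The simulator

The generator reproduces the statistical structure the analyses consume,
not the chemistry that creates it. Peroxynitrite treatment is emulated as a
probabilistic site-assignment process; retention time, isotope patterns
and quantitative reproducibility across replicates are not modeled, so
passing tests demonstrate correctness of the downstream arithmetic and
recoverability of planted effects — not instrument realism.

- **Proteome.** i.i.d. residues from average UniProtKB/Swiss-Prot amino
  acid frequencies; protein lengths normal(450, 150) truncated at 50.
  Real proteomes have compositional autocorrelation this lacks; the motif
  null (below) relies on the i.i.d. property.
- **Nitration.** Each tyrosine is nitrated independently with base rate
  0.05, multiplied by a context bonus (default 3) when any of G/L/P/A/E —
  the small non-polar residues reported to mark nitration-susceptible
  tyrosines — occurs within ±2 residues; probabilities cap at 1. With
  bonus 1 the planted motif vanishes, giving a clean null for the motif
  pipeline.
- **Digestion.** Cleavage C-terminal to K/R, suppressed before proline
  (toggleable), 0–2 missed cleavages, peptide lengths 6–30. Each (tryptic
  peptide × contained site) pair becomes one candidate nitropeptidoform
  carrying a single nitroY.
- **Capture.** Four antibodies × 3 replicates per mode. Protein-level mode
  captures whole proteins with the antibody's capture probability and emits
  all their nitropeptides — no positional bias, so the N-terminal fraction
  sits at the digest baseline (~6–8%). Peptide-level mode captures
  candidates individually, with separate probabilities for position-1 and
  other peptides calibrated against the pool's baseline position-1 fraction
  so that the *expected fraction of distinct position-1 peptidoforms per
  antibody* equals that antibody's `p_nterm_bias`. The calibration is done
  on the replicate-union capture probability (per-replicate draws stay
  independent) because the reported fraction aggregates distinct
  peptidoforms across replicates; calibrating per replicate would bias the
  union-level fraction. Default biases span 0.35–0.65 across the four
  antibodies.
- **Spectra.** Peaks at all b/y m/z (charge 1, plus charge 2 for fragments
  above 900 Da neutral), intensities log-normal (σ = 0.8). A noisy
  "experimental" spectrum and its clean "synthetic" twin share one
  intensity draw, so the noise parameters alone drive score degradation:
  peak dropout 0.10, m/z jitter σ = 0.002 Da, intensity noise CV = 0.25,
  plus 5 uniform contaminant peaks. Validation sets plant a configurable
  decoy fraction (default 0.30) by pairing the clean spectrum with the
  noisy spectrum of a *different* peptidoform; decoy/true labels are kept
  in the ground truth. At the defaults, true pairs score ≳0.9 and decoys
  ≈0, so the 0.7 threshold separates them with ≥95% sensitivity and
  specificity and the pass fraction tracks the planted true-pair fraction.

Everything is deterministic under a fixed seed; independent substreams are
derived per stage so changing one stage's draw count does not disturb the
others.

## Problem sizes

Defaults are desk-scale: 300 proteins for pipeline runs and validation
sets (≈1,700 candidate nitropeptides, enough for 500 validation pairs),
and 4,000–4,200 proteins for the parameter-recovery and motif-recovery
checks, chosen so each antibody's peptide-mode group holds ≥2,000 distinct
peptidoforms and the pooled flanking-context log-odds carry ≥4 standard
errors of signal. The full acceptance script runs in well under a minute
on one CPU.

## Known limitations

- The greedy matcher is not globally optimal for pathological peak
  clusters (see above); real centroided fragment spectra do not reach that
  regime at a 0.01 Da tolerance.
- Decoy pairs occasionally share a terminal fragment (e.g. y1 of
  K/R-terminated peptides), which is why decoy scores are near zero rather
  than exactly zero.
- Protein inference, FDR control, GO/pathway enrichment and vendor raw
  file handling are deliberately outside the package; inputs are MGF,
  FASTA and TSV.
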