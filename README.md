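# nitroscope

Downstream analysis of antibody-based nitrotyrosine (3-nitroTyr) enrichment
proteomics. Tyrosine nitration is an oxidative post-translational
modification (+44.985 Da monoisotopic) formed by reactive nitrogen species
such as peroxynitrite; because it is sub-stoichiometric, global studies
enrich modified proteins or peptides with anti-nitrotyrosine antibodies
before LC-MS/MS. `nitroscope` implements the computational stages that sit
downstream of the database search in such studies, for proteomics
researchers who need them as a tested, scriptable pipeline:

- **Mass and fragment arithmetic** for nitropeptidoforms: modification
  deltas from elemental formulas, neutral/precursor masses, b/y fragment
  series with modification-aware localization.
- **Spectral validation** of experimental identifications against synthetic
  peptide standards by cosine similarity. Both spectra are normalized to
  relative intensity, peaks at or below 2% of the base peak are discarded,
  peaks are matched one-to-one within 0.01 Da into aligned intensity
  vectors *u*, *v*, and the score is

  $$\cos\theta = \frac{\sum_{i=1}^{n} u_i v_i}
  {\sqrt{\sum_{i=1}^{n} u_i^2 \cdot \sum_{i=1}^{n} v_i^2}}$$

  A pair is accepted when the score exceeds 0.7. Mirror-plot data and
  figures are produced per pair.
- **Site cataloging**: peptide-level nitro sites lifted to protein
  coordinates (with tyrosine checks against the FASTA), N-terminal-position
  fractions per antibody and enrichment mode, cross-antibody overlap
  (Venn regions, subset intersections, union counts), and flanking-sequence
  motif matrices (counts / frequencies / log2-odds vs. the proteome
  background) for logo construction.
- **A ground-truthed simulator** that emulates the statistical structure of
  such a study — context-biased nitration (small non-polar residues
  G/L/P/A/E raise susceptibility), tryptic digestion with missed cleavages,
  per-antibody capture with protein-level vs. peptide-level enrichment
  bias, and paired noisy/clean fragment spectra — so every stage is
  testable without any raw-data download.

## Worked example

Run the whole pipeline on a simulated study (300 proteins, 4 antibodies ×
3 replicates in both enrichment modes, 100 validation pairs of which 30%
are planted decoys):

```bash
nitroscope run-all --seed 42 --n-pairs 100 --out demo/
# validation pass fraction 0.670; report at demo/catalog.tsv
```

`demo/n_terminal_fraction.tsv` then holds the per-antibody fractions of
distinct nitro peptidoforms whose nitroY sits at peptide position 1:

```
antibody  mode           n_peptidoforms  n_n_terminal  fraction
AB1       peptide_level  279             96            0.344
AB1       protein_level  1520            97            0.064
AB2       peptide_level  227             103           0.454
...
AB4       peptide_level  158             98            0.620
AB4       protein_level  1604            101           0.063
```

Peptide-level enrichment recovers each antibody's configured N-terminal
bias (defaults span 0.35–0.65), while protein-level capture stays at the
unbiased tryptic baseline (~6%): enriching at the peptide level favors
peptides that *start* with the nitrated tyrosine, a known antibody
behavior this simulator reproduces by construction. The run report
(`demo/run_report.json`) summarizes the validation stage:

```
n_pairs 100, n_passed 67, pass_fraction 0.67,
sensitivity 0.957, specificity 1.0 at threshold 0.7
```

i.e. 67 of 100 pairs exceed cosine 0.7 — close to the planted 70% true-pair
fraction, with decoy pairs scoring near zero. Per-pair scores are in
`demo/validation_scores.tsv`; `--mirrors` additionally renders mirror-plot
PNGs per pair.

All stages are also available as library functions
(`nitroscope.compare_spectra`, `nitroscope.build_catalog`, …) and as
separate subcommands (`simulate`, `catalog`, `sites`, `motif`, `overlap`,
`similarity`, `validate`).

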