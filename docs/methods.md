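# Methods

## The classification model

`ptscan` treats peroxisomal targeting-signal annotation as a deterministic
rule system, not a scored predictor. The underlying assumption is the one
the comparative-survey literature works under: PTS1 function is determined
(to first order) by the identity of the three C-terminal residues, with each
position contributing independently, and the experimental record partitions
residues per position into *high-abundance* (canonical), *low-abundance*
(non-canonical, demonstrated but rare) and *unproven* classes. Upstream
enhancer elements, receptor-binding affinities and piggybacking are outside
the model: the classifier reports tripeptide *structure*, not import
*functionality*. Tripeptides such as SNV> and TNL>, experimentally
functional despite two low-abundance residues, are therefore reported as
`no_obvious_i`; users who need functional overrides should keep their own
exception lists.

### Residue-class table

The default table is:

| position | high (canonical) | low (non-canonical) |
|----------|------------------|----------------------|
| −3       | S, A             | P, T, Q, I, V        |
| −2       | K, R             | N, S, T, Y, H, M, L, Q, F, A |
| −1       | L, M, I          | F, V, Y              |

All other residues are unproven at that position. The low sets are
assembled from the inventory of demonstrated or catalogued non-canonical
tripeptides in the two-species survey setting (PKL>, TKL> fix P and T at −3;
SNL>, SSL>, SYM>, AHL>, SML>, SLM> and the ATS>/SAK> cases fix the −2 set,
including alanine; SRF>, AKV>, SRY> fix the −1 set; QKF>, IFT>, VVA> fix Q,
I and V at −3). Alanine at −2 is included because the survey literature
explicitly treats the middle residue of SAK> as non-canonical; without it
SAK> would fall into the wrong no-obvious sub-category. The table is
config-overridable (JSON, validated for per-position disjointness) because
the published typography marking unproven residues is not fully consistent
and because new experimental demonstrations move residues from unproven to
low. Sequences are upper-cased before lookup; non-standard letters
(X, B, Z, U) are treated as unproven with a warning.

Under this table exactly 12 of the 8000 tripeptides are canonical
(|{S,A}|·|{K,R}|·|{L,M,I}|), and the five labels partition all 8000 — both
properties are asserted against an independently coded brute-force oracle in
the test suite.

### PTS2 matching

The nonapeptide consensus `[RK][LVIQ]xx[LVIHQ][LSGAK]x[HQ][LAF]` is applied
in one of two modes. *Strict* requires every constrained position to
conform. *Relaxed* (the default) requires only the anchor positions
{1, 8, 9} — the invariant basic residue, the invariant H/Q and the terminal
hydrophobic residue — and reports remaining non-conforming positions as
deviations. Relaxed is the default because empirically observed PTS2
domains (e.g. RTx5HL, with threonine at position 2, or domains with S/T at
position 6) violate the strict middle-position sets while being accepted as
PTS2 in the survey literature; strict matching would reject part of the
positive set the propensity tables are built from. Strict matches are by
construction a subset of relaxed matches, property-tested on random
sequences.

The scan window is 40 residues from the N terminus. The literature says
only "N-terminal portion"; 40 comfortably covers every observed plant PTS2
start while keeping incidental matches on background sequence rare. Whole-
sequence scanning (for the transthyretin-like-protein case of an internal
PTS2) is off by default and enabled per call; such matches are flagged
`internal` and do not set the PTS2 summary category when a terminal signal
is present.

### Internal PTS1 and the offset convention

The internal scan reports every canonical or non-canonical tripeptide whose
`end_offset` (residues strictly after the motif) lies in 1..50 — the
observed offsets in plant catalogues are 3, 10 and 13, and 50 leaves
headroom without flooding the report. The notation `QKL-10>` is read as QKL
followed by ten residues; because the count convention is nowhere defined
formally, an `inclusive` alternative (counting the motif's last residue
itself, shifting offsets by one) is selectable in `AnnotatorOptions`.

### Summary precedence

A protein's summary category follows a fixed precedence: an N-terminal PTS2
match wins; otherwise the terminal tripeptide decides `PTS1_canonical` /
`PTS1_noncanonical`; otherwise any internal hit gives `internal_PTS`;
otherwise `none`. Proteins with multiple kinds of evidence (the LACS7
pattern: PTS2 plus terminal SKL>) retain all evidence and carry a
`dual_signal` flag. Catalase-type proteins (summary `internal_PTS`) are
counted *inside* the no-obvious tally and also broken out separately, which
is what reconciles the two renditions of the published no-obvious counts
(10 vs 7 in the reference species, 19 vs 17 in the target species).

## Propensity statistics

Propensity is `100·count/n` per (position, residue), kept internally as an
exact rational. Printed values truncate toward zero at three significant
figures: the published 14-sequence column is reproducible only under
truncation (42.857… prints as 42.8, not 42.9), while terminating values
(68.75, 12.5) are unaffected at the published precision. Column sums of
counts equal n and of propensities equal 100, property-tested. Input
nonapeptides are fixed-length and gap-free, so no alignment step exists.
Ranked reports break count ties alphabetically.

## Integer percentages

Catalogue percentages (`percent_canonical`) use floor, not rounding: the
published pair (68, 56) arises from 74/108 = 68.5 and 55/97 = 56.7 only
under truncation. The rule is scale-invariant and property-tested.

## Synthetic proteomes

The generator emulates the composition of a curated reference catalogue:
default signal mix 0.58 canonical-PTS1, 0.19 non-canonical-PTS1, 0.15 PTS2,
0.02 catalase-type internal, 0.06 signal-free — the proportions of the
reference-species catalogue (74/24/19/3/7 over 127 proteins). Lengths are
uniform on 60–300 residues (typical matrix-enzyme scale); the background is
i.i.d. uniform over the 20 residues, with plant-like frequency vectors
accepted via config. Signals overwrite residues in place: terminal
tripeptides are drawn from the 12 canonical or the 17 catalogued
non-canonical tripeptides, PTS2 domains are strict-consensus instantiations
placed at starts 1–30, and internal motifs default to QKL at end_offset 10.

A uniform i.i.d. background produces targeting-signal look-alikes by chance
(roughly 2% of background proteins end in a canonical or non-canonical
tripeptide; relaxed PTS2 anchors match a random 9-mer with probability
2/20 · 2/20 · 3/20 ≈ 0.15% per start). Rather than rejection-sampling these
away — which would bias the background — every record carries an audit: an
exhaustive scan of the final sequence whose non-embedded hits are listed as
incidental signals in the truth table. Recovery tests then require exact
agreement between the annotator and the truth-plus-audit expectation, making
both recall and precision measurable. Fixed seeds give byte-identical
output.

What the generator does not emulate: real residue composition and
autocorrelation, homology between proteins, ortholog divergence, enhancer
context upstream of PTS1s, and signal-strength variation. Passing recovery
tests therefore demonstrates that the scanning and precedence logic is
exact, not that the rule system is biologically complete.

## Numerical and degenerate-input choices

* Truncation arithmetic runs on `fractions.Fraction`, so printed values are
  exact, not float-rounded.
* Sequences shorter than 3 residues cannot yield a terminal call and raise
  an input error at extraction; internal/PTS2 scans on short sequences
  return empty lists rather than erroring.
* Trailing `*` stop symbols are stripped (with a warning at FASTA read).
* Duplicate FASTA record IDs abort annotation, naming the ID.
* All scans are deterministic; the pipeline writes byte-identical artifacts
  for identical inputs and configuration.

## Problem sizes in the shipped checks

The test suite exercises: all 8000 tripeptides against a brute-force oracle;
1000 random 50–300-mers for partition/conservation; a 1000-protein synthetic
proteome for recovery; 10 000 generated proteins for signal-mix frequency
calibration (within three multinomial standard errors); and 50 random
300-mers for strict ⊆ relaxed containment. These sizes make every check
exhaustive or statistically decisive while keeping the default run fast.

## Known limitations

* The residue-class table encodes a literature snapshot; it is data, not
  learned, and will lag new experimental demonstrations (hence the JSON
  override).
* Relaxed PTS2 matching with three anchors is deliberately permissive;
  on whole-proteome scans it should be treated as a candidate generator,
  not a predictor.
* No modelling of targeting strength, enhancer elements, piggybacking or
  receptor binding; no ortholog inference (the ortholog map is an input).
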