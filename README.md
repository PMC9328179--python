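# ptscan

Rule-based annotation of peroxisomal targeting signals in plant proteomes.

Peroxisomal matrix proteins are imported post-translationally, guided by two
kinds of targeting signal: **PTS1**, a C-terminal tripeptide recognized by
the PEX5 receptor, and **PTS2**, a degenerate N-terminal nonapeptide
recognized by PEX7. A few proteins (the catalase family most prominently)
instead carry an *internal* PTS1-like tripeptide upstream of the C terminus.
`ptscan` implements the classification and scanning rules used in
comparative plant peroxisome-proteome surveys (the *Arabidopsis thaliana* /
*Solanum lycopersicum* setting), so that whole proteomes can be annotated,
tallied and compared reproducibly. It is aimed at plant cell-biology and
organelle-proteomics groups building candidate peroxisome proteome lists for
new species from a reference catalogue.

## The rules

**PTS1.** At each tripeptide position (−3, −2, −1 from the C terminus) the
20 amino acids are partitioned into *high-abundance* (canonical) residues —
the classical consensus `[SA] [KR] [LMI]>` — *low-abundance* (non-canonical)
residues with demonstrated but rare PTS1 function, and *unproven* residues.
The tripeptide label is a total function of the three per-position classes:

| classes at (−3, −2, −1)          | label             |
|----------------------------------|-------------------|
| all high                         | `canonical`       |
| exactly one low, two high        | `non_canonical`   |
| ≥ 2 low, none unproven           | `no_obvious_i`    |
| exactly one unproven             | `no_obvious_ii`   |
| ≥ 2 unproven                     | `no_obvious_iii`  |

**PTS2.** The nonapeptide consensus is
`[RK][LVIQ]xx[LVIHQ][LSGAK]x[HQ][LAF]` (positions 1–9). Because observed
PTS2 domains deviate from the weakly constrained middle positions, the
default matcher runs in *relaxed* mode: only the anchor positions {1, 8, 9}
must conform and other deviations are reported, not disqualifying. Strict
mode is available.

**Internal PTS.** A canonical/non-canonical tripeptide ending 1–50 residues
before the C terminus (catalase's signature is written `QKL-10>`: QKL
followed by ten residues).

**Propensity.** Over a set of n nonapeptides, the propensity of residue r at
position p is `100 · count(p, r) / n` percent; printed values truncate the
decimal expansion toward zero at three significant figures (11/14 → 78.5).

## Worked example

```python
from ptscan import classify_pts1, annotate_protein, compute_propensity, percent_canonical

call = classify_pts1("SNL")
print(call.label, call.classes, sorted(call.low_position))
# non_canonical ('high', 'low', 'high') [-2]
#   -> SNL> carries a single low-abundance residue (N at -2): a non-canonical PTS1

ann = annotate_protein("M" + "RQAALLSHL" + "W" * 90 + "SKL", protein_id="LACS7-like")
print(ann.summary_category, ann.dual_signal, ann.terminal.label)
# PTS2 True canonical
#   -> both a PTS2 domain (RQx5HL at start 2) and a terminal SKL>;
#      the summary takes PTS2 by precedence and flags the dual signal

table = compute_propensity(["RLAALLSHL"] * 11 + ["RLAALLSHF"] * 3)
print(table.propensity(1, "R"), table.printed(9, "L"), table.printed(9, "F"))
# 100.0 78.5 21.4
#   -> R is invariant at position 1; L appears in 11 of 14 nonapeptides at position 9

print(percent_canonical(74, 108), percent_canonical(55, 97))
# 68 56
#   -> truncated integer percentages of canonical PTS1 proteins in two catalogues
```

The command-line surface mirrors the library:

```bash
ptscan simulate -n 100 --seed 7 -o syn            # synthetic proteome + truth table
ptscan annotate syn.fasta -o syn.annotations.tsv  # per-protein annotation TSV
ptscan propensity nonapeptides.txt -o prop.tsv    # positional propensity table
ptscan compare at.tsv sl.tsv -o report.json       # two-species comparative report
ptscan run pipeline.json                          # all-in-one from a JSON config
```

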