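# alnconf

Ensemble-based reliability scoring for protein multiple sequence alignments
(MSAs).

From one set of unaligned sequences, `alnconf` builds a reference alignment
and then generates hundreds of alternative alignments of the same sequences
by jointly perturbing three sources of alignment uncertainty:

1. **guide tree** — the reference's columns are bootstrapped, pairwise
   p-distances re-estimated, and a fresh neighbor-joining guide tree built
   per ensemble member (100 trees by default);
2. **gap-open penalty** — one value per tree, drawn uniformly from a
   configurable range (1–3 in MAFFT-like matrix-scale units by default;
   a 4–16 ClustalW-style preset is available);
3. **co-optimal solutions** — per tree × gap-open combination, several
   head/tail orientations (4 by default) of the progressive merges: a
   "tail" merge aligns both profiles character-reversed and un-reverses the
   result, landing on the opposite extreme co-optimal alignment.

The default ensemble is therefore 100 × 4 = 400 alternatives.  Every
column, residue pair, residue and sequence of the reference is then scored
by its frequency of reproduction across the ensemble:

- **CS** (column score): fraction of alternatives containing an identical
  column (same per-sequence residue ordinals and gap pattern);
- **pair scores**: fraction of alternatives in which a residue pair shares
  a column;
- **SPC**: mean pair score within a column; **residue** and **sequence**
  scores average over pairs and residues.

Each perturbation component can be toggled individually for ablation
experiments.  The package also ships an indel-aware sequence-evolution
simulator (LG substitution model, gamma + invariant-sites rate
heterogeneity, power-law indel lengths capped at min(10% of the sequence
length, 25)) and a benchmarking harness that evaluates reliability scores
against the simulated true alignments with ROC/PR curves and Pearson
correlation to the per-column fraction of correctly aligned pairs.

The alignment engine is internal (progressive Gotoh profile alignment with
occupancy-weighted affine gaps); no external aligner binaries are invoked.

## CLI

```sh
# score the reliability of an alignment of seqs.fasta (400 alternatives)
alnconf score seqs.fasta -o out/
# -> out/reference.fasta, column_scores.tsv, residue_scores.tsv,
#    sequence_scores.tsv, score_summary.json, manifest.json

# single-component ensemble (guide-tree only), custom size and seed
alnconf score seqs.fasta -o out/ --components tree --n-cooptimal 1 \
    --n-trees 200 --seed 7

# simulate a benchmark dataset (true alignment + ungapped sequences)
alnconf simulate -o sim/ --n-taxa 20 --depth 1.0 --root-length 200 --seed 1

# evaluate scores against a known true alignment
alnconf benchmark -o report.json --truth sim/true_msa.fasta \
    --inferred out/reference.fasta --scores out/column_scores.tsv

# full simulate->score->evaluate loop, all component modes, pooled metrics
alnconf benchmark -o report.json --replicates 10 --budget 100 --seed 1

# filter an alignment by a previously computed score directory
alnconf mask out/reference.fasta out/ -o filtered.fasta --column-cutoff 0.93
```

All randomness is controlled by `--seed`; identical seed, config and input
give byte-identical outputs.  Every run writes a `manifest.json` with the
config echo and input checksums.

## Library

```python
import numpy as np
from alnconf import (PerturbConfig, build_reference, generate_alternatives,
                     score_report, read_fasta)

seqs = read_fasta("seqs.fasta")
ref = build_reference(seqs)
alts = generate_alternatives(seqs, ref, PerturbConfig(seed=1))
report = score_report(ref, alts)   # .cs, .spc, .pair_scores, ...
```

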