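# sspkit

Eight-state protein secondary-structure prediction that treats peptides as
molecules: sequences are converted to explicit-hydrogen structural formulae,
described by canonical multilevel atom-neighborhood descriptor strings, and
classified by a naive-Bayes-style one-vs-rest model with empirical Pa/Pi
confidence outputs.

## What it does

- **`sspkit.peptide_chem`** — one-letter sequences → condensed polypeptide
  graphs (neutral termini, explicit hydrogens, deterministic atom order),
  ring perception via bridge detection, and SD-file I/O in the MDL MOL
  V3000 dialect (no atom-count ceiling) with class labels in `SSP_TYPE`
  data fields.
- **`sspkit.mna`** — canonical atom-neighborhood descriptors of any level:
  level 0 is the atom label (`-` prefix marks acyclic atoms), level k
  appends the sorted level-(k−1) descriptors of all bonded neighbors.
  Built bottom-up per level, invariant under atom re-ordering.
- **`sspkit.sspr`** — one-vs-rest training over the eight structure classes
  H, G, I, P, E, C, T, S (β-bridge excluded), evidence score
  `B = mean(2·p̂(a|d) − 1)` with Laplace-style shrinkage to the class prior,
  Pa/Pi from leave-one-out training-score distributions (exact
  count-decrement LOO), Mann–Whitney ROC AUC, descriptor-level sweeps, and
  a versioned JSON model format.
- **`sspkit.dataset`** — classic fixed-column DSSP parsing, maximal-run
  segment extraction with length (4–130) / class / resolution (≤ 2 Å)
  filters, unique-sequence multi-label record assembly, and class
  co-occurrence tables.
- **`sspkit.annotate`** — whole-protein annotation: every 4–30-residue
  window is predicted and each residue inherits the maximal Pa−Pi per
  class; 8→3 state mapping (configurable) and Q3/Q8 scoring.
- **`sspkit.fixtures_cli`** — seeded synthetic labelled peptide sets with
  class-biased residue composition, and the CLI.

## CLI

```sh
# synthetic labelled set (SDF, MOL V3000)
sspkit synth --classes H,E --n-per-class 200 --seed 42 -o train.sdf

# dataset from DSSP output + resolution sidecar
sspkit build-dataset 1abc.dssp --metadata meta.tsv \
    --segments-out segments.tsv -o train.sdf

# train (descriptor level 9 by default), predict, annotate, evaluate
sspkit train train.sdf --level 9 -o model.json
sspkit predict-peptides query.fasta --model model.json -o predictions.tsv
sspkit annotate-protein protein.fasta --model model.json \
    --min-delta 0.7 -o annotation.tsv
sspkit eval test.sdf --model model.json
```

`predict-peptides` writes one row per (peptide, class) with B, Pa, Pi,
Pa−Pi and the Pa>Pi flag; `annotate-protein` writes per-residue best
classes and all eight deltas (positions with best delta below
`--min-delta` are shown as `.`).

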