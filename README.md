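# ptmtok

Sequence-based prediction of post-translational-modification (PTM) sites in
which *known* modification sites are injected into the input as extra
amino-acid tokens (`@`, and `&` when a second residue class or modification
type needs its own symbol). Candidate sites are encoded as fixed-length
windows over a 24-token alphabet, embedded, and classified by a small
convolutional network; labeling known sites this way lets the model exploit
modification crosstalk between nearby residues.

The package covers the full workflow:

- **`ptmtok.alphabet`** — token alphabet (`-`=0, the 20 canonical amino
  acids alphabetically = 1..20, `U`=21, mod tokens next), label application,
  window extraction with center masking, vectorize/devectorize.
- **`ptmtok.datasets`** — candidate enumeration, 1:1 negative balancing,
  80/10/10 random splits with an exact-duplicate test guarantee, ungapped
  k-mer identity filtering, 10-fold Monte Carlo resampling.
- **`ptmtok.model`** — the embedding → 2D conv → max-pool → dense → dropout
  → sigmoid classifier, implemented directly on NumPy (manual backprop,
  Adam, binary cross-entropy, early stopping with best-epoch restore), so
  exact input-embedding gradients are available for attribution.
- **`ptmtok.evaluation`** — exact Mann–Whitney AUC, step-interpolated
  AUPRC, CV aggregation, paired with/without-labels significance testing.
- **`ptmtok.interpret`** — integrated gradients on the embedded input
  (right-Riemann path integral), per-position attribution profiles, K-means
  clustering of attribution tensors, per-cluster position-frequency
  matrices for logo rendering.
- **`ptmtok.proximity`** — frequency of known sites at each signed offset
  from candidate sites, with a uniform/periodic/decaying shape classifier.
- **`ptmtok.simulate`** — synthetic proteomes with planted motifs and
  tunable modification-crosstalk signal, so everything is testable offline.
- **`ptmtok.io` / `ptmtok.cli`** — FASTA (with optional inline `@`/`&`
  tokens), site TSV, split manifests, prediction CSV, and the CLI.

## CLI

```sh
# make a synthetic dataset (FASTA + site TSVs + ground-truth manifest)
ptmtok simulate --out-dir sim/ --n-proteins 300 --seed 1

# train your own model with 10-fold Monte Carlo CV, with and without
# known-site labeling, and report the paired comparison
ptmtok tyom --fasta sim/proteins.fasta --sites sim/positives.tsv \
    --k 53 --folds 10 --seed 1 --compare-labels --force --out-dir run/

# score new sequences; inline @/& tokens mark known modified residues
ptmtok predict --fasta query.fasta --model run/model.stk --out pred.csv

# attribution and proximity analyses
ptmtok interpret --fasta sim/proteins.fasta --sites sim/positives.tsv \
    --model run/model.stk --out-prefix ig/run
ptmtok proximity --fasta sim/proteins.fasta --sites sim/positives.tsv \
    --window 26 --out hist.tsv
```

Site TSVs have columns `protein_id`, `position` (1-based), `mod_type`.
Every command writes a `*.run.json` manifest (input hashes + seeds) and
re-runs reproduce outputs byte-identically.

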