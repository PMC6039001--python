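# helixenv

Statistical analysis of the nanoenvironment of fixed-length α-helices.

Same-length helices are grouped by multi-assigner consensus (PDB / DSSP /
Stride roles), positionally aligned with 32-residue flanks, and the
inside-vs-outside "signal" of per-residue structural descriptors is
detected with:

- per-position profiles (mean, SD, SEM, occupancy%, helical%), sequence
  logo matrices and inside/outside ECDFs;
- sliding-window two-sample tests (pooled-variance Student's t and
  two-sample Kolmogorov–Smirnov) over the aligned region, for one window
  size or a 1…2L sweep;
- inverse-coefficient-of-variation normalized-difference classification
  of descriptors (none / moderate / strong at |Δ| thresholds 0.1 and 1.0);
- MANOVA of inside-vs-outside residues after a Shapiro–Wilk normality
  filter and a greedy pairwise-correlation filter (cutoff 0.9), reported
  with Wilks' lambda, Pillai's trace, Hotelling–Lawley trace and Roy's
  largest root, plus descriptor-usage ranking and region quality
  assessment.

A synthetic-data module generates chains, three assigner views with
controlled disagreement, and descriptor tables with a known inside mean
shift, so the whole pipeline is testable offline. A 69-name descriptor
registry and a per-length helix-count reference table ship as package
data.

## CLI

All commands work on a data directory holding `sequences.fasta`,
`annotations.tsv` (chain_id, assigner, annotation) and `descriptors.tsv`
(chain_id, residue_index, one column per descriptor) — the layout
`helixenv simulate` writes.

```sh
helixenv simulate --n-chains 50 --helix-length 12 --inside-effect 1.0 \
    --seed 1 --out data/
helixenv datamart --data data/ --consensus pdb-dssp-stride --redundancy 0.7
helixenv align   --data data/ --length 12 --flank 32
helixenv scan    --data data/ --length 12 --descriptor d1 --test t
helixenv census  --data data/ --length 12
helixenv manova  --data data/ --length 12
helixenv assess  --data data/ --chain C01 --region 40:51 --threshold 1e-6
helixenv run     --data data/ --out results/   # full pipeline + manifest
```

Exit codes: 0 success, 2 input error, 3 degenerate data (with `--strict`).

## Layout

```
src/helixenv/
  synthetic.py     synthetic cohorts and assigner views
  datamarts.py     DSSP parsing, helix extraction, consensus, clustering,
                   per-length datamarts
  alignment.py     positional alignment, profiles, logo, ECDF
  univariate.py    t / KS tests, sliding-window scans, signal census
  multivariate.py  normality + correlation filters, MANOVA, region verdicts
  pipeline.py      stage driver with manifests
  cli.py, io.py, registry.py
  data/            descriptor registry, reference helix counts
tests/             pytest suite (tests/test_acceptance.py holds the
                   acceptance criteria)
scripts/acceptance.py
```
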