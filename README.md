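# aretools

A toolkit for engineering mRNA stability through the 3'UTR:

- **scan** — locate stabilizing AU-rich-element (ARE) motifs (`UUUUU` poly-U
  tracts, `UUGCAUGG`, `CCUUACAC`) and destabilizing motifs (`AUUUU`, `CCUC`,
  `CUGC`, `UAAGUUAU`, `UAACUUAU`, `GUAAAUAG`) in 3'UTR sequences, with BED6
  export and a per-sequence stability profile.
- **design** — rewrite every stabilizing element to its destabilizing
  counterpart (`UUUUU→CCUC`, `UUGCAUGG→CUGC`, `CCUUACAC→UAAGUUAU`), apply
  optional single-residue edits (M5 C→U, M6 U→C, M11 A→U preset; positions
  are user-supplied), and iterate to a fixed point with zero stabilizing
  motifs left.
- **assemble** — build the synthetic gBlock in fixed part order
  BstBI site – poly-A – promoter – insert – poly-A – BamHI site, with
  validation for internal restriction sites, non-ACGT characters, and
  homopolymer synthesis limits.
- **fit-decay** — ΔCt fold-enrichment and one-phase exponential decay
  fitting (`Y(t) = (Y0 − plateau)·e^(−kt) + plateau`, half-life `ln2/k`)
  with optional replicate bootstrap confidence intervals.
- **simulate** — synthetic fixtures: planted-motif UTRs with airtight
  ground truth, and 4SU-style pulse-chase qPCR Ct tables with log-normal
  noise.

All coordinates are 0-based, half-open, plus-strand. The internal alphabet
is RNA; DNA input/output is converted at the boundary.

## CLI

```sh
aretools scan --fasta utr.fasta --bed hits.bed --profile profile.tsv
aretools design --fasta utr.fasta --out utr.desare.fasta \
    --edits edits.tsv --report report.tsv
aretools assemble --insert utr.desare.fasta --promoter promoter.fasta \
    --polya5 30 --polya3 30 --out construct.fasta --parts parts.tsv
aretools simulate utr --length 300 --plant UUUUU@10 --plant CCUUACAC \
    --seed 7 --out utr.fasta --truth truth.tsv
aretools simulate chase --half-life 1.5 --cv 0.1 --seed 1 --out ct.tsv
aretools fit-decay --ct ct.tsv --target construct --reference ACTB \
    --out fit.tsv --boot 1000 --seed 1
```

Exit codes: 0 success, 1 usage/validation error, 2 data error (stale
rewrite plan, unmapped motif, unpaired qPCR wells). The motif catalog can
be overridden with `--config` (flat `key = value` file: `stabilizing`,
`destabilizing`, `replace.<MOTIF>` entries); `edits.tsv` has columns
`label`, `position`, `from`, `to`.

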