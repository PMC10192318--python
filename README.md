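# apoploss

Tools for studying apoptotic-gene loss in parasite assemblies:

- **Decontamination** (`apoploss.decontam`): host-genome contig exclusion
  (best hit > 85% identity and e-value < 1e-75), three-way contig
  classification from best hits against a target-clade and a contaminant
  database (e-value at least 100-fold smaller and bit score at least
  1.5-fold larger decides; otherwise "not clear"), and GC-content rescue of
  the ambiguous group (low-GC contigs routed to the target set, with an
  automatic KDE-valley cutoff estimator and the published preset cutoffs).
- **Sequence I/O and ORFs** (`apoploss.seqio_gc`): strict FASTA parsing, GC
  content over unambiguous bases, and six-frame stop-to-stop ORF extraction
  with a 70-aa default floor.
- **Hit tables** (`apoploss.hits`): 12-column tabular (outfmt-6-style) and
  per-sequence domain-scan (tblout-style) parsers, with deterministic
  per-query best-hit reduction.
- **Loss matrix** (`apoploss.lossmatrix`): a curated taxon × actor-category
  catalogue (caspases, multidomain Bcl-2, BH3-only, death receptor, adaptor
  protein, IAP, APAF-1, p53, cytochrome C, calpain), its boolean presence
  matrix with per-taxon retention counts, a monotone loss-gradient check,
  and category assignment from domain complements via an editable rule
  table.
- **Pseudogene scan** (`apoploss.pseudoscan`): in-frame stop codons inside
  a candidate's structural domain, split into inside-insertion vs
  outside-insertion relative to a reference alignment, with a conserved
  sub-span upgrade.
- **Synthetic data** (`apoploss.synthdata`): seed-deterministic mixed
  assemblies (low-GC target mode ~0.28 vs high-GC contaminant mode ~0.55),
  paired hit tables with a tunable e-value/bit-score separation knob, and
  aligned pseudogene fixtures with planted insertions and stops.

## CLI

One subcommand per stage; every stage reads and writes plain files.

```sh
apoploss simulate --n-target 1000 --n-contam 1000 --seed 42 --out-dir sim/
apoploss run --assembly sim/assembly.fasta \
    --target-hits sim/target_hits.tsv --contam-hits sim/contam_hits.tsv \
    --gc-auto --out-dir run/                      # full decontamination
apoploss host-filter --assembly asm.fa --host-hits host.tsv --out-dir hf/
apoploss classify --assembly asm.fa --target-hits t.tsv --contam-hits c.tsv --out labels.tsv
apoploss gc-cutoff --assembly asm.fa
apoploss orfs --fasta run/target_contigs.fasta --min-len 70 --out-prefix orfs/orfs
apoploss matrix --out-prefix matrix/actors --render   # packaged catalogue
apoploss gradient --taxa Hydra,Polypodium,Malacosporea,Myxosporea --out gradient.tsv
apoploss pseudoscan --alignment aln.faa --candidate-id candidate \
    --domain-span 11:120 --conserved-span 41:109 --out report.tsv
apoploss run-all --config config.yaml
```

`run-all` takes a YAML config (sections: `inputs`, `host_filter`,
`classifier`, `gc`, `orfs`, `matrix`, `pseudoscan`, `output`, `run`) and
writes every stage's outputs plus a manifest with input checksums and
per-stage record counts under the output directory.

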