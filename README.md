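# rdhfp

Strain-resolution toolkit for organohalide-respiring communities. It covers
the computational pipeline from reductive-dehalogenase (rdhA) sequences to a
minimum count of co-existing *Dehalococcoides mccartyi* strains:

1. **seqalign** — FASTA I/O, affine-gap global alignment (Gotoh) and percent
   identity (PID = identical columns / residue-residue columns).
2. **ortholog** — ortholog-group assignment as single-linkage components at
   PID strictly above 0.90, with reference-registry label inheritance.
3. **tree** — neighbor-joining from 1 − PID distances, midpoint rooting,
   Newick round-tripping.
4. **primers** — ungapped in-silico primer screening with IUPAC degenerate
   codes, mismatch counts and amplicon-length prediction.
5. **qpcr** — log-linear standard curves, Cq → absolute copies, duplicate /
   two-dilution QC, volume-derived method detection limits; censoring is
   propagated, never zero-filled.
6. **fingerprint** — per-sample rdhA/16S ratio profiles, decade abundance
   bins, Pearson similarity on log10 ratios and two-way UPGMA clustering
   with heatmap-table export.
7. **strains** — model-based minimum strain count: the ratio vector is
   explained as binary gene-content × abundances (sum 1); exact smallest-k
   search with a subset-sum lower bound and co-localization candidates.
8. **synth** — synthetic communities and qPCR plates with known truth
   (acceptor-driven selection, Cq-scale Gaussian noise, detection floors).

## CLI

```bash
rdhfp simulate       --config sim.yaml --out-dir fixtures/
rdhfp qpcr-quant     --plate fixtures/plate.csv --meta fixtures/meta.csv --out m.tsv
rdhfp fingerprint    --measurements m.tsv --out fp.tsv
rdhfp cluster        --measurements m.tsv --axis both --out-prefix clust
rdhfp infer-strains  --measurements m.tsv --epsilon 0.05 --kmax 5 --out strains.json
rdhfp og-assign      --fasta seqs.faa --threshold 0.90 --out membership.tsv
rdhfp tree           --fasta seqs.faa --out tree.nwk
rdhfp align          --in seqs.faa --out align.tsv
rdhfp primer-screen  --primers primers.tsv --fasta genes.fna --out screen.tsv
```

Plate CSV columns: `well,sample_id,target,cq,dilution_factor,is_standard,standard_copies`
(empty cq = no amplification). Sample metadata CSV:
`sample_id,volume_filtered,elution_volume_ul,template_volume_ul,matrix`
with matrix `culture_per_mL` or `groundwater_per_L`.

## Notes

- The minimum-strain number is a model-based bound, assuming one 16S copy
  and at most one copy of each rdhA per genome, and a complete assay panel.
- "Below detection" is an upper bound everywhere: censored genes bin as
  `nd`, never as ratio 0, and a censored 16S makes the whole profile
  undefined.
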