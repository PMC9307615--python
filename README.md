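# scvartools

Single-cell variant-profile analysis for haploid (bacterial) genomes:

- **Replicate-concordance filtering** — a variant is kept only when the
  identical call (contig, position, ref, alt) appears in ≥ 2 single-cell
  replicates of the same condition, removing whole-genome-amplification
  artifacts (`scvartools.concordance`).
- **Codon-level effect annotation** — synonymous / non-synonymous /
  intragenic-noncoding / intergenic / multi-bp classification from first
  principles with the bacterial translation table
  (`scvartools.effect_annotator`).
- **Ka/Ks statistics** — genome-wide raw-count ratios and per-gene ratios
  normalized by Nei–Gojobori-style site opportunity restricted to
  positions covered in ≥ 2 replicates; cross-condition gene-of-interest
  selection (`scvartools.kaks_analysis`).
- **Non-randomness tests** — per-gene combinatorial probability 1/C(N, K),
  a genome-as-continuum Monte Carlo randomization with pluggable
  clustering statistics, Friedman + Nemenyi rank tests, and two-sample
  t tests (`scvartools.null_models`).
- **Noncoding characterization** — intragenic/intergenic tallies,
  cross-condition sharing, distance-to-nearest-gene distributions,
  substitution spectrum with GC-direction rollup, sliding-window hotspot
  report (`scvartools.noncoding_analysis`).
- **Synthetic data** — a deterministic generator producing a full input
  bundle (FASTA + GFF3 + per-replicate VCF 4.2 + depth TSV + read
  classification TSV) with planted hotspot structure and ground truth, so
  the whole pipeline is testable offline (`scvartools.synthetic_data`).

## CLI

```sh
# generate a synthetic input bundle
scvartools simulate --seed 1 --out bundle/

# merge replicates of one condition
scvartools merge --condition Ground_UV \
    --vcf bundle/vcf/Ground_UV_rep1.vcf --vcf bundle/vcf/Ground_UV_rep2.vcf \
    --vcf bundle/vcf/Ground_UV_rep3.vcf --vcf bundle/vcf/Ground_UV_rep4.vcf \
    --out merged.tsv

# Monte Carlo clustering null
scvartools nulltest --fasta bundle/genome.fasta --gff3 bundle/genes.gff3 \
    --vcf Ground_UV merged_or_replicate.vcf \
    --iterations 1000000 --seed 17 --out null.json

# everything at once, from a YAML config (see RunConfig in scvartools.pipeline)
scvartools run-all --config run.yaml
```

Other subcommands: `annotate`, `kaks`, `noncoding`, `metrics`. All
coordinates are 0-based half-open internally; GFF3/VCF conventions are
converted at the I/O boundary only.

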