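# sigsel

Genome scans for **signatures of selection** in replicated, bidirectionally
selected line pairs, with a forward-time simulator that reproduces the full
experimental design end to end.

The scan statistic is the intra-class correlation **θ** (an Fst estimator):
per SNP, a 0/1 allele indicator per gamete is decomposed by a nested
random-effects model — line, replicate within line, sample within
replicate × line, gamete within sample — with method-of-moments variance
components that support unbalanced cells and missing calls. θ over a sliding
window of `w` SNPs is the ratio of summed between-line components to summed
totals. Genome-wide significance comes from max-statistic permutations of the
design labels over gametes and over whole individuals, taking the stricter of
the two critical values.

## What is included

| module | purpose |
| --- | --- |
| `sigsel.simulate` | multi-founder intercrossed base population, replicated bidirectional within-family truncation selection with rotational mating and relaxed generations, shallow (~5×) read simulation with per-read errors, causal-locus truth set |
| `sigsel.genotypes` | VCF / read-count TSV I/O, pooled allele frequencies per line × replicate, presence/absence genotype calls, depth-cap and error-screen locus filters, founder-line pooling |
| `sigsel.ld` | EM two-locus haplotype frequencies and R², LD-decay profile with automatic window calibration (LD_25), four-gamete-rule haplotype blocks, minor-gamete-frequency spine search |
| `sigsel.scan` | nested variance components, windowed θ, genome-wide permutation thresholds (gamete / individual / both), signature calls, pairwise Fst summaries within and across replicates |
| `sigsel.annotate` | gene-region partition from GFF3 (10 kb promoter, exon, UTR, 150 bp intron–exon junctions, deep intron, intergenic), signature-to-region assignment, densities per Mb, per-gene region-count correlations with permutation p-values |
| `sigsel.drift` | divergent fixed/lost counts per scope, OLS drift regression `Lost = b0 + b1·Fst`, per-scope FDR `(N − b0)/N`, depth-based heterozygote-miscall calculator |
| `sigsel.pipeline` / `sigsel.cli` | one-config orchestration with a checksummed manifest and Manhattan-plot export |

## CLI

```bash
sigsel simulate --seed 1 --outdir out/sim
sigsel filter --readcounts out/sim/simulated_readcounts.tsv --out out/filtered.tsv
sigsel ld --vcf out/sim/simulated.vcf --design out/sim/design.tsv --out out/ld.tsv
sigsel blocks --vcf out/sim/simulated.vcf --design out/sim/design.tsv --out-prefix out/blocks
sigsel scan --vcf out/sim/simulated.vcf --design out/sim/design.tsv \
    --window 7 --permutations 1000 --gwp 0.01 --mode both --seed 1 \
    --out-prefix out/scan
sigsel fdr --readcounts out/sim/simulated_readcounts.tsv \
    --design out/sim/design.tsv --out out/fdr.tsv
sigsel run-all --config pipeline.yaml --outdir out/full --seed 1
```

`run-all` accepts a YAML config mirroring `sigsel.pipeline.PipelineConfig`
(optionally with a nested `sim:` section of `SimConfig` fields) and writes
every artifact plus a `manifest.json` with SHA-256 checksums; runs are
deterministic given the seed.

## Conventions

* VCF positions are 1-based inclusive and kept 1-based on the in-memory
  locus map; BED exports are 0-based half-open.
* Genotypes are unphased; the two "gametes" of a sample are its allele
  copies in arbitrary order (the scan statistic depends only on dosages).
* Method-of-moments components may be negative and are not truncated;
  monomorphic loci are excluded from windows.
* One master seed drives every stage; per-replicate simulator streams are
  spawned deterministically from it.
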