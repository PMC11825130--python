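# sweepshare

Tested, reusable pipeline for studying locally restricted versus shared
selective sweeps across multiple resequenced populations, plus asymptotic
McDonald–Kreitman estimation of the adaptive fixation proportion α.

The package covers five stages, each usable as a library module and as a
CLI subcommand:

| stage | module | what it does |
| --- | --- | --- |
| synthetic data | `sweepshare.synth` | coalescent haplotypes under piecewise-constant demographies (msprime), parametric hard-sweep injection with an exact truth table, replicate samples, and uSFS count tables with known true α(x) |
| scan | `sweepshare.scan` | composite sliding-window statistic μ = μ_var · μ_sfs · μ_ld (span deficit × extreme-SFS excess × flank-LD contrast, with quality-mask rescaling of μ_var), plus π and Tajima's D |
| regions | `sweepshare.regions` | GCV cubic-spline smoothing of μ tracks, outlier thresholds from the pooled quantile of neutral coalescent simulations, gap merging into sweep regions, and replicate-concordance hyperparameter grid search |
| sharing | `sweepshare.sharing` | single-linkage clustering of regions across populations, private/shared bookkeeping, replicate-based accuracy P = 1 − (nS/nP1 + nS/nP2)/2, exact accuracy-adjusted hypergeometric sharing tests, Benjamini–Yekutieli correction |
| MK α | `sweepshare.mk` | 0-fold/4-fold degeneracy annotation from FASTA+GFF3, two-outgroup polarization, uSFS construction, per-bin α = 1 − (d0/d)(p/p0), and fits of α(x) = a + b·e^(−cx) (pooled, per-group, or partial pooling) |

## CLI

All commands share `--config PATH --seed INT --outdir PATH --threads INT
--log-level LEVEL`. A single YAML config drives the run; outputs are TSV/BED
files stamped with the package version, config hash, and seed.

```bash
sweepshare simulate --config config.yaml --seed 1 --outdir out   # VCFs + truth table
sweepshare scan     --config config.yaml --seed 1 --outdir out   # per-population mu tracks
sweepshare regions  --config config.yaml --seed 1 --outdir out   # BED regions + thresholds
sweepshare grid     --config config.yaml --seed 1 --outdir out   # hyperparameter search
sweepshare share    --config config.yaml --seed 1 --outdir out   # clusters + sharing tests
sweepshare mk       --config config.yaml --seed 1 --outdir out   # degeneracy, uSFS, alpha fits
```

Minimal config sketch:

```yaml
dataset:
  chrom: "1"
  L: 10000000
  populations:
    - {label: pc, subspecies: maize, n_hap: 20, replicate: true,
       demography: {epochs: [[0, 10000]], mu: 3.0e-8, r: 1.6e-8}}
    - {label: ame, subspecies: teosinte, n_hap: 20,
       demography: {epochs: [[0, 10000]], mu: 3.0e-8, r: 1.6e-8}}
  scenarios:
    - {center_bp: 5000000, footprint_halfwidth_bp: 200000,
       drop_max: 0.9, extreme_max: 0.8, carriers: [pc, ame]}
scan: {W: 24, maf_min: 0.05}
regions: {quantile: 0.999, merge_dist: 50000, threshold_reps: 100}
grid: {W: [10, 24, 50], quantile: [0.99, 0.999], merge_dist: [50000, 100000]}
share: {P: 1.0}
mk: {fasta: genome.fa, gff3: genes.gff3, vcf: pop.vcf, n: 20}
```

Conventions: VCF/GFF3 coordinates are 1-based per their standards; BED and
all region outputs are 0-based half-open. Replicate-flagged populations are
simulated once at twice the sample size and split into disjoint halves
(`<label>_rep1`, `<label>_rep2`).

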