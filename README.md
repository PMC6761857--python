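# sweepscan

Selective-sweep scanning toolkit for sparse diploid SNP panels (GBS-style
data). It implements a complete, reproducible analysis chain:

1. **Synthetic cohorts** (`sweepscan.simulate`) — multi-scaffold bi-allelic
   SNP panels for two or more populations diverging under the
   Balding–Nichols Beta model, with implanted low-heterozygosity sweep
   regions, high-differentiation regions, per-genotype missingness, and a
   controlled fraction of sites violating named hard filters. Identical
   configs (including seed) produce byte-identical output files.
2. **Variant filtering** (`sweepscan.filtering`) — GATK-style hard filters
   (QD < 2, FS > 60, MQ < 40, QUAL < 30, MQRankSum < −12.5,
   ReadPosRankSum < −8; missing annotations never remove a record), a
   two-pass depth filter (DP ≥ 5 and within 3 SD of the mean), removal of
   excluded scaffolds / indels / multi-allelic sites, Ts/Tv before and
   after, and optional two-caller set intersection.
3. **Genotype QC** (`sweepscan.qc`) — MAF (< 5%) and call-rate (< 95%) site
   filters with three-bucket accounting, greedy sliding-window LD pruning
   (indep-pairwise 50/10/0.1 semantics, audited post-condition), and
   per-sample call-rate / IBS duplicate checks.
4. **Diversity statistics** (`sweepscan.diversity`) — per-sample observed
   heterozygosity and moment inbreeding F̂, the unadjusted A_jk genomic
   relatedness matrix, and the second-order rate-of-change (ΔK) table for
   choosing a cluster number from replicate log-likelihoods.
5. **Selection scans** (`sweepscan.scan`) — pooled heterozygosity
   Hp = 2·Σn_MAJ·Σn_MIN/(Σn_MAJ+Σn_MIN)² in 50-kb windows with 25-kb step,
   Z-transformed with median centering and sample SD; windowed
   Weir–Cockerham Fst between two cohorts combined as Σa/Σ(a+b+c);
   empirical-tail significance (0.1% default) and merging of overlapping
   significant windows into regions. Windows with fewer than two SNPs are
   discarded.
6. **Region annotation** (`sweepscan.annotate`) — GFF3/BED gene loading,
   ≥1-bp half-open region–gene intersection, background gene sets from all
   tested windows, and an optional hypergeometric enrichment stand-in.
7. **Pipeline** (`sweepscan.pipeline`) — one YAML config drives
   simulate → filter → QC → diversity → scans → annotation, with a
   deterministic JSON + text run report embedding the realized cutoffs.

## Command line

```bash
# simulate a cohort
sweepscan simulate --config sim.yaml --outdir out/sim

# filter a VCF
sweepscan filter --vcf in.vcf --out filtered.vcf --report filter_report.tsv

# marker/sample QC (use --no-maf for the Hp-panel regime)
sweepscan qc --vcf filtered.vcf --samples samples.tsv --out out/qc

# diversity + relatedness, and cluster-number scoring
sweepscan diversity --vcf filtered.vcf --samples samples.tsv --out out/div
sweepscan deltak --likelihoods likelihoods.tsv

# selection scans
sweepscan scan-hp  --vcf filtered.vcf --samples samples.tsv \
    --scaffold-lengths scaffolds.tsv --tail 0.001 --out out/hp
sweepscan scan-fst --vcf filtered.vcf --samples samples.tsv \
    --scaffold-lengths scaffolds.tsv --pop-a packing --pop-b racing --out out/fst

# gene annotation of candidate regions
sweepscan annotate --regions out/hp.regions.bed --windows out/hp.windows.bed \
    --genes genes.gff3 --out out/genes

# everything from one config
sweepscan run --config run.yaml
```

A minimal `run.yaml`:

```yaml
outdir: out/run1
seed: 17
simulate:
  scaffolds: [[scafA, 600000], [scafB, 400000]]
  populations: [[packing, 18], [racing, 14]]
  snp_density: 0.0025
  F_divergence: 0.03
  sweep_regions:
    - {scaffold: scafA, start: 200000, end: 320000, population: all, fixation_level: 0.97}
  missing_rate: 0.02
  info_fail_fraction: 0.05
fst_pair: [packing, racing]
thresholds:
  tail_fraction: 0.001
```

Replace the `simulate:` block with `vcf:`, `sample_map:`, `genes:` and
`scaffold_lengths:` paths to run on real data. All coordinates follow the
standard conventions: VCF/GFF3 1-based, BED and internal windows/regions
0-based half-open.

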