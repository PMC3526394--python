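# bsamap

Bulk-segregant analysis (BSA) of pooled exome sequencing for forward
genetics: call putative SNPs from wildtype- and mutant-pool pileups,
scan for loss of heterozygosity (LOH) to localise a recessive mutation,
and design the CAPS/RFLP markers used for fine mapping.

## The problem and the method

In a mapping cross, carriers of a recessive mutation from a mutagenized
strain (N) are outcrossed to a divergent mapcross strain, and the
intercrossed progeny are phenotype-sorted into a mutant pool and a
wildtype pool. At markers unlinked to the mutation both pools stay
heterozygous; at markers linked to it the mutant pool loses
heterozygosity — every mutant embryo is N-homozygous at the causal
locus, and nearby markers hitchhike. Sequencing each pool and comparing
per-position allele fractions therefore localises the mutation without
any prior mapping information.

`bsamap` implements the analysis from samtools-pileup input:

- **Pooled SNP calling.** At every position with ≥ 10 reads in *both*
  pools, a putative SNP is called if (i) the wildtype pool's major
  allele fraction (MAF — the most frequent base's share of A/C/G/T
  reads) lies in [0.50, 0.75], the heterozygous signature; or (ii) the
  wildtype and mutant major alleles differ. A call is classed
  homozygous in the mutant pool when its mutant MAF ≥ 0.90.
- **LOH scan.** For each region — a whole scaffold in fragmented
  assemblies, or non-overlapping 0.5 Mb windows on chromosome-scale
  scaffolds — the homozygosity ratio is

      r = nh / nt

  where nt is the number of putative SNPs in the region and nh the
  number homozygous in the mutant pool. Regions with fewer than 20
  SNPs are excluded to suppress noise from falsely called sites, and
  the remainder are ranked by r; the top regions are the candidate
  interval. High-r regions on more than one scaffold flag a likely
  reference misassembly.
- **Fine mapping.** For SNPs in candidate regions the package finds
  restriction enzymes whose recognition site is created or abolished by
  the SNP (CAPS/RFLP markers, genotypable by PCR + digest on a gel),
  and converts recombinant counts into genetic distance,
  `cM = 100 · recombinants / meioses`, with 2 meioses per scored
  mutant embryo.
- **Cross simulator.** A built-in generator simulates the whole design
  (F2 intercross with Haldane recombination, phenotype-sorted pools,
  Poisson sequencing depth, base-call error) and emits standard pileups
  plus truth tables, so every stage is testable at desk scale.

## Worked example

Simulate a three-scaffold cross with the causal locus at sA:1,250,000,
call SNPs, and scan:

```sh
cat > cross.json <<'EOF'
{
  "scaffolds": {"sA": 2000000, "sB": 2000000, "sC": 2000000},
  "snp_spacing_bp": 10000,
  "causal": ["sA", 1250000],
  "n_mut_embryos": 50, "n_wt_embryos": 50,
  "depth_mean": 30.0, "error_rate": 0.002, "cm_per_mb": 1.2,
  "seed": 42
}
EOF
bsamap simulate --config cross.json --outdir sim
bsamap call sim/wt.pileup.gz sim/mut.pileup.gz --out-tsv calls.tsv --out-vcf calls.vcf
bsamap scan calls.tsv sim/scaffolds.tsv --outdir scan
```

The caller reports

    examined 596 joined sites; 590 putative SNPs (210 homozygous in MUT)

and `scan/ranking.tsv` begins

    chrom  start    end      mode    nt  nh  ratio  excluded
    sA     1        500000   window  60  60  1      0
    sA     1500001  2000000  window  53  53  1      0
    sA     1000001  1500000  window  51  51  1      0
    sA     500001   1000000  window  46  46  1      0

every window of the causal scaffold shows complete loss of
heterozygosity (r = 1), while the unlinked scaffolds sit near r = 0 —
with 50 mutant embryos (100 meioses) the whole 2.4 cM scaffold is
within the mapping resolution, which is why fine mapping then proceeds
with RFLP markers and more embryos. `scan/misassembly.json` confirms
the LOH signal is confined to one scaffold (`"raised": false`), and

```sh
bsamap distance --recombinants 13 --meioses 1300
# 1
```

converts a marker's recombinant count over 650 embryos into 1 cM.

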