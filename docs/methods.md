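# Methods

## Model and procedure

`bsamap` analyses a recessive mapping cross sequenced as two
phenotype-sorted pools. The genetic model: a mutagenized strain N
carries the mutation; F1 carriers (N/mapcross) are intercrossed; a
mutant embryo is N-homozygous at the causal locus, so both of its
chromosomes are informative meioses. At a marker whose recombination
fraction with the causal locus is θ, a mutant-pool chromosome carries
the mapcross allele with probability θ; a wildtype-pool chromosome
carries the N allele with probability (1 + θ)/3, because phenotypically
wildtype embryos are het or mapcross-homozygous at the causal locus in
the 2:1 Mendelian conditional ratio. Unlinked markers (θ = 1/2) are at
50/50 in both pools.

The pipeline stages, in run order:

1. **Pileup decoding** (`pileup_io`). Six-column samtools pileup text
   (the common subset of classic `pileup` and single-sample `mpileup`
   output, plain or gzip) is reduced to per-base substitution counts.
   Strand case is merged — the calling criteria use total allele
   fractions with no strand term. Deleted bases, reference skips and N
   calls never count toward an allele: the MAF denominator is
   substitution reads only. Base qualities are ignored (quality
   trimming is assumed upstream). Positions are 1-based internally;
   BED export converts to 0-based half-open at the boundary. If a
   bases column decodes to fewer symbols than the depth column, the
   decoded counts are trusted and the discrepancy logged rather than
   failing the run.
2. **SNP calling** (`snp_caller`). Sites with ≥ `min_depth` (default
   10) reads in both pools are tested: WT MAF in
   [`wt_maf_lo`, `wt_maf_hi`] (defaults 0.50, 0.75, both endpoints
   inclusive) *or* differing major alleles — a pure OR; criterion (ii)
   applies regardless of the WT MAF. Mutant-pool homozygosity is
   MAF ≥ `hom_threshold` (default 0.90, inclusive). Major-allele ties
   break alphabetically (A < C < G < T) for determinism; tied sites can
   therefore satisfy criterion (ii) asymmetrically and are flagged in
   the output (`tie` column). The reference base plays no role in
   calling and is carried only for VCF export.
3. **LOH scan** (`loh_scan`). Scaffolds no longer than
   `long_scaffold_cutoff` (default = the window size, 0.5 Mb) are one
   region; longer scaffolds are tiled with non-overlapping windows,
   the final short window retained and still subject to exclusion.
   Exclusion is strictly nt < `min_region_snps` (default 20): nt = 20
   is kept. Ranking is by ratio descending with deterministic
   tie-breaks (nt descending, then coordinates ascending). The
   excluded genome fraction is reported as a log metric.
4. **Fine mapping** (`rflp`, `linkage`). Differential restriction
   sites are found by scanning both allele variants of a SNP's flank
   against an IUPAC enzyme panel (both strands for non-palindromic
   sites; a palindromic site counts once per position). Genetic
   distance uses the direct recombination-fraction estimate with no
   map function: at the sub-cM distances of fine mapping, r.f. ≈ cM to
   well below scoring error. Meioses default to 2 per mutant embryo
   (configurable). The misassembly flag collects scaffolds holding any
   non-excluded region with ratio ≥ a threshold (default 0.9) and is
   raised when more than one qualifies, since one recessive locus
   cannot produce independent near-complete LOH on unlinked scaffolds.

## Simulator: what it emulates, and what it does not

`simulate` draws marker maps (exponential spacing, mean
`snp_spacing_bp`; the causal position is always a marker), gametes
(sequential Markov walk with Haldane switch probabilities — no
crossover interference, constant map density `cm_per_mb`), embryos
(rejection sampling to the configured pool sizes; every mutant embryo
N-hom at the causal marker, wildtype embryos kept as drawn), and reads
(Poisson depth per marker per pool, reads sampling the pool's 2n
chromosomes uniformly, uniform miscall errors at `error_rate`). Exome
sparsity is modelled by emitting marker positions only; monomorphic
reference positions can be added for parser stress. An optional block
relocation renames a marker interval's coordinates onto another
scaffold (genotypes untouched, destination length extended), emulating
a reference misjoin.

The truth table stores the analytic expectations above per marker, so
tests compare against closed forms rather than hard-coded numbers.

Not modelled: read-level artefacts (mapping bias, duplicates, indels),
capture efficiency variation, unequal per-embryo DNA contribution,
crossover interference, and multiple mutant alleles at the causal
locus. Passing tests therefore demonstrate the estimator logic and its
sampling behaviour, not robustness to alignment artefacts in real
libraries.

## Default study conditions and problem sizes

The defaults — 10 scaffolds × 2 Mb, spacing 10 kb (~2,000 markers), 50
embryos per pool, depth 30, error 0.002, 1.2 cM/Mb — are a desk-scale
rendition of a pooled exome mapping experiment in a diploid vertebrate
(pool sizes of ~50 tadpoles, ~30× pooled coverage, ~1 cM/Mb map
density). The test suite and the acceptance script use 20 seeded
replicates of these conditions; single-purpose tests use smaller
crosses (2–3 scaffolds, 10–30 embryos) chosen so each statistical
assertion retains ≥ 3-sigma headroom.

## Mapping resolution at these pool sizes

With 50 mutant embryos the mutant pool holds 100 meioses, so the
expected number of recombinant chromosomes within a 0.5 Mb window span
(θ ≈ 0.006 at 1.2 cM/Mb) is below one, and a pool frequency of 0.99
still reads as MAF ≥ 0.9 at depth 30. Consequently *every* window of
the causal scaffold typically saturates at r = 1 and the ranked scan
identifies the causal scaffold essentially always, but cannot single
out the causal window among its tied neighbours: resolution is
~100/meioses ≈ 1 cM ≈ 0.8 Mb, larger than a window. This is inherent
to the statistic, not an implementation artefact, and it is why fine
mapping proceeds by genotyping individual embryos with RFLP markers,
where hundreds of embryos give sub-cM resolution. The suite asserts
scaffold-level recovery as the property these pool sizes support; the
window-level recovery rate is reported by the acceptance script.

## Numerical and design choices

- Haldane's map function is used throughout because it composes
  exactly across intermediate markers (recombination fractions over
  adjacent intervals combine to the Haldane fraction of the summed
  distance), giving closed-form oracles for any marker pair.
- Statistical checks aggregate one probe marker per distance per
  replicate: chromosomes are then independent Bernoulli draws and the
  binomial standard error is exact. Aggregating all markers in a
  distance bin would share chromosomes between markers and
  overdisperse.
- Zero-coverage pileup records use the `0 * *` placeholder convention
  on write and decode to empty counts on read.
- RFLP digest arithmetic: cut positions use the enzyme's cut offset
  when known and the site midpoint otherwise; fragment lengths are for
  gel-resolvability triage, not precise digest maps. `fragments_uncut`
  is the full digest of the non-cutting allele — when the flank holds a
  constitutive site for the same enzyme, both alleles are cut there and
  only the differential site is reported. Fragment lengths always sum
  to the flank length on both alleles.
- Recombinant scoring counts recombinant *chromosomes* (het embryo → 1,
  mapcross-hom embryo → 2) against 2 meioses per embryo, so
  `100 · recombinants / meioses` is the standard recombination
  fraction; an embryo is flagged recombinant when not N-homozygous.
- Degenerate inputs: `major_allele` refuses all-zero counts (callers
  depth-filter first); regions with nt = 0 have an undefined ratio and
  are excluded; duplicate or unsorted pileup positions are errors that
  name the offending position.

## Known limitations

Single-sample 6-column pileup only (no multi-sample mpileup); SNPs
only, no indel calling; no probabilistic genotype likelihoods — the
caller is the deterministic threshold rule by design; no smoothing or
significance model on the LOH ratios (regions are ranked raw); primer
design is out of scope (the RFLP module reports whether a differential
site leaves a configurable end margin, default 50 bp, so a 100–250 bp
amplicon is feasible).
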