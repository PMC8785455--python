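# Methods

## Genotype model and quality control

Genotypes are coded 0 (hom-ref), 1 (het), 2 (hom-alt), −1 (missing) in a
sites × samples int8 matrix; coordinates are 1-based inclusive throughout,
with BED's 0-based half-open convention converted at the file boundary.
Site QC retains autosomal biallelic SNVs that are polymorphic among called
genotypes and have call rate ≥ 0.90 both across the cohort **and within every
population**; the within-population rule exists because a site well-called
overall but poorly called in one group would bias between-group homozygosity
comparisons. "Polymorphic" means at least one reference and one alternate
allele observed among called genotypes — the conventional reading.
Autosomes are an explicit chromosome list in `FilterConfig`, never a name
heuristic. When per-genotype read depth (FORMAT/DP) is present, genotypes
below `min_depth` (default 8×) are set missing *before* call rates are
computed; this per-genotype masking is the implementable analogue of a
sample-level minimum-coverage rule and is the default of the two defensible
interpretations. Sites failing several rules are counted against the first
rule in the order: autosome, biallelic SNV, overall call rate,
per-population call rate, polymorphism. The filter is idempotent.

## ROH calling

The scanning statistic follows the established sliding-window design: with
`window_snp` = 50, a window is homozygous iff #het ≤ `window_het` (default 3)
and #missing ≤ `window_missing` (default 5). Each SNV's hit fraction divides
by the number of **fully contained** windows only; a chromosome shorter than
one window is a single truncated window. This edge rule is not dictated by
any published description, so it was chosen for simplicity and testability,
and the optimized implementation is checked against a naive
window-enumerating reference on randomized instances.

Eligibility is hit fraction ≥ `window_threshold` (0.05) **and** a non-het
call; missing genotypes are neither het nor hom — they count against
`window_missing`, do not break a run, and are included in a segment's
`n_snv` span count (`n_hom` tracks called homozygotes separately). Runs
split where consecutive SNVs are > `max_gap_kb` (1,000 kb) apart; a run is a
segment iff n_snv ≥ `min_snp` (100), length ≥ `min_kb` (100 kb, inclusive,
with length = end − start + 1 bp) and length/n_snv ≤ 50 kb/SNV. All gates
are inclusive comparisons. No LD pruning is applied anywhere on the ROH
path — pruning thins exactly the homozygous stretches the scan must see.

`max_genome_coverage` re-runs the caller on an all-homozygous
pseudo-individual over the real site map and divides the callable length by
L_AUTO (Σ per chromosome max−min+1 of SNV positions). It is the recommended
sanity check when tuning `window_het`/`min_kb`: a parameter set that cannot
reach ≈1 on the map in hand will underestimate F_ROH mechanically.

## F_ROH, length classes and time

F_ROH = Σ L_ROH / L_AUTO. L_AUTO defaults to the filtered site map's span
and can be overridden (`GOAT_L_AUTO_KB` = 2,465,617 kb is exported for
goat-scale data). Each segment belongs wholly to the class of its total
length; classes are left-closed right-open in Mb ([0.1,0.3) … [5.0,∞)), a
boundary-ownership choice made here because printed class labels do not
state it, with an extra leading `<0.1` class so the decomposition always
sums exactly to the total. Time mapping: g = 50/L(Mb) from the expected IBD
segment length 100/(2g) cM at 1 cM ≈ 1 Mb; years multiply by the generation
interval (default 3 years, typical for managed goat herds). Nucleotide
diversity divides Σ 2p̂(1−p̂)·n/(n−1) by the genome span in bp (WGS
convention; a variant-sites-only denominator is a flag) — the estimator is a
standard unbiased choice, not a claim about any particular pipeline's exact
formula.

## ROH islands

Per-SNV in-ROH fractions use the full group size as denominator (sites
already passed the within-population call-rate filter, which keeps these
comparisons unbiased). Islands are maximal runs of consecutive SNVs at
fraction ≥ 0.80; "at least 80%" is read inclusively. `min_island_snvs` = 2
suppresses singleton SNVs, which are almost surely noise at WGS density; no
bp-gap merging of adjacent islands is applied (configurable, default 0).
Island bounds are SNV positions, not midpoints between flanking SNVs. The
pooled step thresholds the pooled-individual fraction (not the mean of breed
fractions); the pooled fraction is exactly the sample-size-weighted mean of
per-population fractions, which is asserted as an invariant. Classification
against the wild group flags an island when its mean wild fraction over
member SNVs is < 0.55. Gene profiles average fractions over island SNVs
inside each gene (gene ∩ union of per-population islands); flags use strict
inequalities (> 0.75 high, < 0.25 low), and a gene without island SNVs is
reported with a missing value, never dropped. The 1-Mb window matrix marks a
population's window when one of its island SNVs falls inside it.

## Candidate-variant screen

Genotype counts are exact per population; allele frequencies use called
alleles only. Group frequencies pool genotype counts over member
populations, making the pooled value the count-weighted mean of population
frequencies. The divergence flag |domestic − wild| ≥ 0.5 makes explicit a
selection step that is otherwise done by eye; 0.5 is a deliberate,
configurable convention, not an estimated quantity. Variant effects
(missense annotations) are input metadata and never computed.

## Synthetic cohorts

The generator emulates the features the analysis relies on: irregular dense
SNV maps (uniform positions, sorted, deduplicated), per-population
Beta(0.8, 0.8) background alt frequencies with Hardy–Weinberg genotypes,
autozygous tracts from an alternating renewal process — tract lengths
Exponential with mean 50/g Mb, gap lengths scaled so the stationary covered
fraction equals the target autozygosity, started at stationarity, merged
after sampling so the truth is well-defined — single-haplotype homozygosity
inside tracts, planted islands where every sample of the affected
populations is homozygous for the same per-site allele, then hom→het errors
and missingness applied independently. One `numpy` generator seeded once
drives all sampling in a fixed documented order, so cohorts are reproducible
bit-for-bit.

Default conditions are a desk-scale cohort: 4 modern populations plus a
wild outgroup (10 samples each), one 30-Mb chromosome at 1 SNV/kb, target
autozygosity 0.25 at g = 10 (mean tract 5 Mb). At that tract scale a 30-Mb
genome holds only ~1.5 renewal cycles, so a single cohort's mean realized
autozygosity has standard deviation ≈ 0.2 per sample; recovery checks
therefore average over replicate cohorts (the Monte-Carlo design the
generator's own invariants use) rather than asserting on one draw.
What passing these tests shows — and does not show: the caller recovers
exponential-length IBD tracts and fixed regions under HW backgrounds with
low genotyping error; real data add LD structure, variable recombination
and error rates, and reference biases that no test here exercises.

## Numerical and degenerate-input choices

Zero-record VCF regions yield an empty matrix with the full roster; an
empty post-filter matrix warns rather than errors. `target_autozygosity` 0
and 1 short-circuit to no tracts / one whole-chromosome tract. A population
absent from the matrix, a candidate variant with swapped alleles, an
unsorted VCF, a roster sample missing from the header, and a malformed
BED/GFF3 line are all hard errors naming the offender. Problem sizes in the
test suite (5–30 Mb genomes, 300–1,000 SNVs/Mb, tens of samples, 5–20
replicates) were chosen as the smallest scales at which the statistical
assertions have comfortable Monte-Carlo margins.

## Known limitations

No consensus/overlap ROH pooling across individuals, no haplotype-based
selection statistics, no variant-effect prediction, no phasing or
coalescent realism in the simulator. The `.hom` writer reports PHET as 0 by
construction (eligible SNVs are never het); PHOM derives from the stored
called-homozygote count.
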