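# Methods

This note documents the models, conventions and design choices behind
`paralogsift`: what each stage computes, why the defaults are what they are,
what the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## The problem

After a whole-genome duplication, some chromosome-arm pairs re-diploidize
slowly and remain nearly identical in sequence. Reads from the two copies of
such a region can collapse onto a single reference position. A fixed
difference between the copies (a paralogous sequence variant, PSV) then looks
like a SNP that is heterozygous in essentially every individual; a variant
segregating on one collapsed copy (a multisite variant, MSV) produces
dose-dependent mixed-allele signals. Both must be removed from a SNP database
intended for diploid genotyping, and both leave two statistical fingerprints:
heterozygosity in doubled-haploid (DH) individuals, which are homozygous at
every single-copy locus, and excess heterozygosity / Hardy–Weinberg deviation
in outbred samples.

## Filter cascade

Stages run in a fixed order (QUAL → LC → DP → NS) with per-stage entering/
passing counts. All four predicates are pure per-site functions given fixed
masks and indel positions, so the surviving *set* is order-independent; the
order only attributes removals in the ledger.

* **QUAL** — keep bi-allelic single-base variants with phred-scaled quality
  strictly greater than `min_qual` (default 30, i.e. error probability
  < 10⁻³) and no indel anchor within `indel_distance` bases (default 4,
  measured as |Δpos| ≤ 4 on the VCF anchor positions; the conservative
  reading that removes borderline sites). Indels are parsed and carried to
  this stage so proximity can be evaluated, then discarded.
* **LC** — drop SNPs inside low-complexity regions. The masker is DUST-style:
  in a sliding window of `dust_window` = 64 bases, score
  Σᵢ cᵢ(cᵢ−1)/2 / (w−3) over the trinucleotide counts cᵢ; windows scoring
  strictly above `dust_threshold` = 2 are masked, overlapping masked windows
  merged, and N runs always masked. This reproduces the role of the
  conventional masker (~10% of a repeat-bearing genome masked at default
  tract densities), not any particular implementation bit-for-bit.
* **DP** — drop sites whose read depth summed over samples exceeds
  `max_depth` = 1,500 (≈ 24.6 reads per sample across 61 samples, roughly
  1.6× the expected coverage); collapsed repeats accumulate excess depth.
  Depth is the sum of allelic depths (AD) when available, else per-sample DP
  — one internal definition, since callers report depth differently.
* **NS** — re-call genotypes from allelic depths, then require a callable
  genotype in at least `min_samples` samples (default 58 of 61; for other
  panel sizes ceil(0.95·N), preserving the 58/61 ≈ 0.95 design fraction).

**Genotype rule.** A heterozygote requires ≥ 2 reads supporting the alternate
allele and ≥ 1 supporting the reference. Only the heterozygote rule is given
by the study design; homozygotes are defined symmetrically (≥ 2 reads of the
observed allele, 0 of the other) and everything else is missing. This makes
the genotype function total and testable; the symmetric rule is validated by
truth-genotype recovery in the simulator tests. By default the pipeline
re-calls genotypes from AD rather than trusting caller GT fields
(`recall_genotypes=False` restores the caller's view).

## Doubled-haploid screen

`dh_het_count` counts called heterozygotes among the DH lines (missing calls
never count — missingness is the NS filter's job). A site is flagged as a
putative PSV/MSV when the count reaches `threshold` (default 2): one DH
heterozygote is compatible with residual maternal heterozygosity, two or more
are not. The threshold sweep reports, for every minimum count 1..n_DH, the
flagged-set size, the mean observed heterozygosity of flagged loci among the
50 outbred fish, and the share with exact-test HWE p < 0.05. Rows are
labelled both as "Het > k" and by minimum count; flag sets are nested across
thresholds by construction.

**Exact HWE test.** The conditional exact test: given the genotype counts'
allele totals, the probability of each heterozygote count of matching parity
is computed from log-Γ factorials, and the p-value sums configurations no
more probable than the observed one (with a 10⁻¹⁰ log-scale tie guard). The
exact test is used, not a chi-square approximation, because per-population
sample sizes in this design are 4–12. The test suite verifies the
implementation against an independent exact-rational enumeration for every
genotype table with n ≤ 40 and random tables at every n up to 200.

**Arm density.** Flagged loci are assigned to chromosome arms by interval
lookup; arms come from an arm table (name, chrom, start, end, duplicated
flag). Without one, each chromosome is a single arm. The duplicated
(delayed-rediploidization) arms are expected to concentrate flagged loci.

## Two-caller concordance

Sites are keyed by (chrom, pos). Categories: unique to caller A, unique to
B, same-site-same-ALT, same-site-different-ALT; a REF mismatch at a shared
position is folded into different-ALT, since both callers share one reference
and a mismatch reflects representation differences. Two percentages follow
the two customary denominators: same-ALT share of the *combined* set
(A-only + B-only + shared), printed at integer precision, and different-ALT
share of the *shared* sites, printed at three decimals; both round half-even.
The pipeline's trusted core is the same-site-same-ALT intersection (caller
A's records carry the genotypes downstream).

## Population statistics

* **MAF** counts two alleles per called sample (61 fully called samples give
  122 alleles) and folds at 0.5. DH samples are included in the global
  spectrum's denominators.
* **Per-population polymorphism** restricts, per population, to sites with a
  called genotype for every fish in it; a site is polymorphic when both
  alleles are observed there. Reported: counts, integer percentage, mean MAF
  and mean observed heterozygosity over polymorphic sites (two decimals),
  computed within the population. The pooled DH group is reported as one row.
* **π** uses the per-site unbiased estimator (n/(n−1))·2p(1−p) with n the
  called allele count, accumulated over 20 kb windows and divided by the true
  window width (trailing partial windows by their real length); the genome
  mean is the unweighted mean over all windows, empty windows included.
* **SNP density** reports bases-per-SNP as a *truncated* integer
  (floor(length/count)) per chromosome and genome-wide — truncation, not
  rounding, is the convention this table follows.

## Effect annotation

Gene models come from GFF3 (gene, mRNA/transcript, exon, CDS, UTRs). Each
bi-allelic SNP yields one effect per overlapping transcript, plus
upstream/downstream records for genes within 5 kb, with `intergenic_region`
as the fallback, from a fixed 20-term Sequence Ontology vocabulary with
HIGH/MODERATE/LOW/MODIFIER impacts. Coding effects use strand-aware codon
extraction and comparison (stop_gained/lost/retained, start_lost,
initiator_codon_variant for substitutions to the alternative initiators
CTG/GTG/TTG, missense, synonymous). Splice donor/acceptor are the first/last
two intronic bases; the splice region covers intronic bases 3–8 (within the
CDS the codon term takes precedence over the splice-region label).
splice_region_variant is assigned LOW impact. A premature-start gain is
called when the substitution creates an ATG in the 5′ UTR's local window.
These boundary conventions are configurable defaults; effect *counts* are
counts of effects, not SNPs.

## Synthetic-data generator

The generator produces every input the pipeline consumes, with a fixed seed
giving byte-identical files.

**Design (defaults).** 61 samples: 11 DH lines plus outbred populations
shaped like the target study (seven populations of 4, one 12-fish
aquaculture population, five 2-fish populations). Genome: 2 chromosomes × 2
arms of 120 kb (480 kb total — chosen so the full pipeline runs in seconds
while every table keeps its natural shape; all densities are per-bp, so
behaviour scales). One duplicated arm pair (chr1q–chr2p) diverged at
2×10⁻³/bp. Planted variants: true SNPs at 8×10⁻³/bp genome-wide with
ancestral frequencies Beta(0.5, 0.5) and Balding–Nichols per-population
frequencies at F_ST = 0.1; PSVs at 1.5×10⁻³/bp and MSVs at 0.8×10⁻³/bp on
duplicated arms only. Residual DH heterozygosity 0.005 per line per site.
Low-complexity tracts (homopolymer/dinucleotide repeats of 100–400 bp) at
3×10⁻⁴ starts/bp ≈ 10% of the genome; indels at 2×10⁻⁵/bp; 0.2% of sites get
10× depth (collapsed-repeat artifacts for the DP filter).

**Reads.** Per-sample mean coverage is drawn uniformly between the 8×
minimum and 22× (mean 15×); per-site depth is Poisson at that mean; allelic
reads are binomial at the expected alternate fraction — dosage/2 at true
SNPs, dosage/4 at MSVs (two copies of each of two collapsed paralogs), and
~1/2 at PSVs — floored at the base-error rate 5×10⁻⁴ (error-driven alternate
reads at homozygous sites; the value reflects that callers count only
quality-filtered reads in AD). PSV fractions are deliberately *not* exactly
1/2: a per-site mean from Beta(8, 8) with per-sample Beta noise at
concentration 40 models the dispersed allelic ratios of real collapsed
paralogs (mapping bias, copy-number differences). This dispersion is what
grades the DH-heterozygote count across PSV loci and stretches the threshold
sweep into its characteristic profile; with exact 1/2 fractions every PSV
would be heterozygous in all 11 DH lines and the sweep would be flat.

**Callers.** Both callers see the same read data. Each independently misses
sites at a drop rate derived in closed form from the configured target
combined-set concordance (default 0.80) and the caller-unique false-site
rate (0.01) — solving x² = c·(x² + 2x(1−x) + 2f) for the inclusion
probability x — so the ~80% concordance is a configuration input rather than
a tuned outcome. Shared sites disagree on ALT at 4×10⁻⁴; each caller draws
its own QUAL with 5% of sites below the 30 threshold; indels are emitted
identically by both callers.

**What is not emulated.** No read-level simulation or alignment: collapsed
paralogy is modelled directly at the read-count level, which is where the
filters operate. No linkage disequilibrium, no demographic history beyond
Balding–Nichols population differentiation, no genotyping platform error
beyond the binomial read model, no MNPs/complex events, and the toy gene
models attached for annotation are coordinate scaffolds, not biological gene
structures. Passing tests therefore demonstrate correctness of the filters
and estimators under the assumed sampling model, and the qualitative
structure of the screen's behaviour — not performance on real alignments,
where mapping artifacts are more heterogeneous.

## Validation design

* Exact reproduction of every summary statistic that is pure arithmetic on
  the published count tables (density rates including the truncation-pinning
  cases, concordance percentages under both denominators, polymorphism
  ratios, the rare-allele share).
* Oracle equivalence for the algorithmic cores: the window masker against a
  brute-force dictionary scorer; the exact HWE test against exact-rational
  enumeration (exhaustive to n = 40, sampled to n = 200 — full enumeration
  of every table to n = 200 is ~1.3 M tables and adds no coverage beyond the
  per-n sampling); the concordance classifier against a brute-force join;
  the codon classifier against exhaustive translation of all 576 single-base
  codon changes.
* Parameter recovery on the synthetic study (seed 1): DH screen sensitivity
  ≥ 0.9 and specificity ≥ 0.99 against planted truth; threshold-sweep
  structure (strictly decreasing counts, strictly increasing flagged-locus
  heterozygosity, HWE-deviation share increasing — tested to the one-locus
  resolution of a percentage over shrinking denominators); flagged density
  concentrated on duplicated arms; caller concordance within 2 points of the
  configured 80%.
* Estimator recovery on an artifact-free companion configuration with fully
  concordant callers (so designed losses do not confound the measurement):
  genome-mean π within 10% of the truth-genotype value, and ≥ 99% of true
  SNPs surviving the cascade.

The default test suite and the acceptance script each complete in well under
a minute on one CPU at these problem sizes (~4.4 k planted sites × 61
samples per study).

## Known limitations

* The screen cannot separate PSVs from MSVs or from loci present in more
  than two copies; all are flagged together, as the downstream use (removal
  from a diploid genotyping database) requires.
* MSVs at low frequency on the segregating copy can escape the 2-of-11 DH
  threshold (they are heterozygous in few DH lines); this bounds the
  screen's sensitivity and is visible in the simulator truth comparisons.
* The HWE signature is computed on the pooled 50 outbred fish; population
  structure (Wahlund effect) deflates heterozygosity slightly and makes the
  pooled test conservative for true SNPs.
* With only ~300–400 flagged loci at desk scale, sweep percentages have a
  resolution of ~0.3 points; the published tables, at ~10⁶ loci, print
  smooth monotone columns.
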