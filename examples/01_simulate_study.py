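"""Generate a synthetic resequencing study and look at its design.

The generator emulates a 61-sample whole-genome SNP discovery panel for a
genome with residual tetraploidy: 11 doubled-haploid (DH) lines plus outbred
populations, a genome whose duplicated arm pair carries planted paralogous
sequence variants (PSVs) and multisite variants (MSVs), per-sample allelic
read depths, and two imperfectly concordant variant-caller outputs.
"""

from collections import Counter

from paralogsift import SimConfig, simulate

cfg = SimConfig(seed=42)
res = simulate(cfg)

print(f"genome: {len(res.build.chrom_lengths)} chromosomes, "
      f"{sum(res.build.chrom_lengths.values()):,} bp")
print(f"duplicated arm pairs: {res.build.duplicated_pairs}")
print(f"samples: {len(res.sheet)} "
      f"({len(res.sheet.dh_indices)} DH lines, "
      f"{len(res.sheet.non_dh_indices)} outbred fish)")

classes = Counter(v.cls for v in res.truth.variants)
print(f"planted variants: {dict(classes)}")
print(f"caller A: {len(res.callset_a)} records, caller B: {len(res.callset_b)}")
print()
print("Each planted PSV presents as a ~50/50 read mixture in every sample —")
print("the signature of two collapsed paralogous loci — while true SNPs")
print("segregate with population-specific allele frequencies.")
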