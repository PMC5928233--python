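"""Compare two variant callers' outputs site by site.

Sites called by both programs at the same position with the same alternate
allele form the trusted core of a SNP database; the two summary percentages
use the combined-set and shared-site denominators respectively.
"""

from paralogsift import SimConfig, classify_sites, concordance_summary, simulate

res = simulate(SimConfig(seed=42))
a = [s for s in res.callset_a if s.is_biallelic_snp]
b = [s for s in res.callset_b if s.is_biallelic_snp]

records = classify_sites(a, b)
s = concordance_summary(records)

print(f"caller A only:        {s.n_a_only:>6}")
print(f"caller B only:        {s.n_b_only:>6}")
print(f"same site, same ALT:  {s.n_same_alt:>6}")
print(f"same site, diff ALT:  {s.n_diff_alt:>6}")
print()
print(f"same-ALT share of combined sets: {s.pct_same_alt_of_combined:.0f}%")
print(f"ALT disagreement among shared sites: {s.pct_diff_alt_of_shared:.3f}%")
print()
print("The ~80% combined-set concordance mirrors a two-pipeline discovery")
print("design; the small ALT-disagreement fraction reflects algorithmic")
print("differences between haplotype-based and pileup-based calling.")
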