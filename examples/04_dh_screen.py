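"""The doubled-haploid heterozygosity screen for paralogous variants.

A DH individual is homozygous at every single-copy locus, so heterozygous
calls in >= 2 of the 11 DH lines flag a site as a putative PSV/MSV (one DH
heterozygote is not trusted because of rare residual maternal
heterozygosity). The threshold sweep shows the trade-off, and flagged loci
carry the expected signature among outbred fish: excess observed
heterozygosity (Ho) and deviation from Hardy-Weinberg equilibrium (HWE).
"""

from paralogsift import (
    SimConfig,
    arm_density,
    dh_screen,
    simulate,
    threshold_sweep,
)
from paralogsift.pipeline import run_all

res = simulate(SimConfig(seed=42))
run = run_all(res.callset_a, res.callset_b, res.sheet, res.build,
              sequences=res.sequences)
survivors = run.retained + run.flagged

print(f"{'threshold':<10}{'flagged':>8}{'mean Ho':>9}{'% HWE dev':>11}")
for row in threshold_sweep(survivors, res.sheet):
    print(f"{row.label:<10}{row.n_flagged:>8}{row.mean_outbred_ho:>9.2f}"
          f"{row.pct_hwe_deviation:>10.0f}%")

print("\nflagged-locus density by chromosome arm (per Mb):")
for arm in arm_density(run.flagged, res.build):
    tag = "  <- delayed rediploidization" if arm.is_delayed_rediploidization else ""
    print(f"  {arm.arm:<7}{1e6 * arm.per_bp:>8.1f}{tag}")
print("\nFlagged loci pile up on the duplicated arm pair, as expected for")
print("collapsed paralogs after whole-genome duplication.")
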