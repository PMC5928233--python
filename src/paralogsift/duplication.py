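"""Doubled-haploid heterozygosity screen for paralogous sequence variants.

A doubled haploid (DH) individual is homozygous at every single-copy locus,
so a heterozygous call in a DH line marks a position where reads from two
collapsed paralogous loci pile up — a paralogous sequence variant (PSV) or
multisite variant (MSV) — rather than a true allelic polymorphism. Because
rare residual maternal heterozygosity does occur in DH lines, a single DH
heterozygote is not trusted: the default screen flags a site when at least
two of the DH lines are called heterozygous.

The module also quantifies the signature of the flagged class among outbred
samples — excess observed heterozygosity and deviation from Hardy–Weinberg
equilibrium by the exact conditional test — and the concentration of flagged
loci on duplicated (delayed-rediploidization) chromosome arms.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .model import Arm, GenomeBuild, Genotype, SampleSheet, VariantSite


class PsvClassification(enum.Enum):
    RETAINED_SNP = "retained_snp"
    PUTATIVE_PSV_MSV = "putative_psv_msv"


@dataclass
class DhScreenResult:
    chrom: str
    pos: int
    dh_het_count: int
    classification: PsvClassification
    outbred_ho: float
    hwe_p: float


@dataclass
class ThresholdSweepRow:
    label: str  # "Het > k" (or "Het = n_DH" for the top row)
    min_het: int  # the equivalent minimum DH-heterozygote count
    n_flagged: int
    mean_outbred_ho: float
    pct_hwe_deviation: float  # % of flagged loci with exact-test p < 0.05


@dataclass
class ArmDensity:
    arm: str
    length: int
    n_flagged: int
    is_delayed_rediploidization: bool

    @property
    def per_bp(self) -> float:
        return self.n_flagged / self.length if self.length else 0.0


def dh_het_count(site: VariantSite, sheet: SampleSheet) -> int:
    """Number of DH samples called heterozygous; missing calls do not count."""
    return sum(
        1
        for i in sheet.dh_indices
        if site.per_sample[i].genotype is Genotype.HET
    )


def classify_psv(
    site: VariantSite, sheet: SampleSheet, threshold: int = 2
) -> PsvClassification:
    """Flag a site as putative PSV/MSV iff >= ``threshold`` DH heterozygotes."""
    if dh_het_count(site, sheet) >= threshold:
        return PsvClassification.PUTATIVE_PSV_MSV
    return PsvClassification.RETAINED_SNP


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact conditional test of Hardy–Weinberg equilibrium.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of the same parity, the probabilities of configurations no more
    likely than the observed one. Monomorphic input gives p = 1. Valid at the
    small per-population sample sizes (4–12 fish) of this study design, where
    a chi-square approximation would not be.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_hom_ref + n_het  # reference allele count
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # possible het counts share the parity of the rare allele count
    hets = range(rare % 2, rare + 1, 2)

    def logp(h: int) -> float:
        haa = (n_a - h) // 2 if n_a >= n_b else (n_b - h) // 2
        # counts of the two homozygote classes given h hets
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(hom_rare + 1)
            - gammaln(hom_common + 1)
            - gammaln(h + 1)
            + h * math.log(2.0)
            + gammaln(n_a + 1)
            + gammaln(n_b + 1)
            - gammaln(2 * n + 1)
        )

    lp_obs = logp(n_het)
    total = 0.0
    for h in hets:
        lp = logp(h)
        if lp <= lp_obs + 1e-10:
            total += math.exp(lp)
    return min(total, 1.0)


def observed_heterozygosity(
    site: VariantSite, indices: Sequence[int]
) -> float | None:
    """Het calls / non-missing calls within a sample subset (None if no
    calls)."""
    n_called = n_het = 0
    for i in indices:
        g = site.per_sample[i].genotype
        if g is Genotype.MISSING:
            continue
        n_called += 1
        if g is Genotype.HET:
            n_het += 1
    if n_called == 0:
        return None
    return n_het / n_called


def mean_observed_heterozygosity(
    sites: Iterable[VariantSite], indices: Sequence[int]
) -> float:
    vals = [observed_heterozygosity(s, indices) for s in sites]
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else 0.0


def _genotype_counts(site: VariantSite, indices: Sequence[int]) -> tuple[int, int, int]:
    counts = {Genotype.HOM_REF: 0, Genotype.HET: 0, Genotype.HOM_ALT: 0}
    for i in indices:
        g = site.per_sample[i].genotype
        if g in counts:
            counts[g] += 1
    return counts[Genotype.HOM_REF], counts[Genotype.HET], counts[Genotype.HOM_ALT]


def outbred_hwe_p(site: VariantSite, sheet: SampleSheet) -> float:
    aa, ab, bb = _genotype_counts(site, sheet.non_dh_indices)
    if aa + ab + bb == 0:
        return 1.0
    return hwe_exact_test(aa, ab, bb)


def dh_screen(
    sites: Sequence[VariantSite],
    sheet: SampleSheet,
    threshold: int = 2,
    compute_hwe: bool = True,
) -> tuple[list[VariantSite], list[VariantSite], list[DhScreenResult]]:
    """Partition sites into retained SNPs and putative PSVs/MSVs.

    Returns (retained, flagged, per-site results); retained + flagged is an
    exact partition of the input.
    """
    retained: list[VariantSite] = []
    flagged: list[VariantSite] = []
    results: list[DhScreenResult] = []
    outbred = sheet.non_dh_indices
    for s in sites:
        count = dh_het_count(s, sheet)
        cls = (
            PsvClassification.PUTATIVE_PSV_MSV
            if count >= threshold
            else PsvClassification.RETAINED_SNP
        )
        ho = observed_heterozygosity(s, outbred)
        results.append(
            DhScreenResult(
                chrom=s.chrom,
                pos=s.pos,
                dh_het_count=count,
                classification=cls,
                outbred_ho=ho if ho is not None else 0.0,
                hwe_p=outbred_hwe_p(s, sheet) if compute_hwe else 1.0,
            )
        )
        (flagged if cls is PsvClassification.PUTATIVE_PSV_MSV else retained).append(s)
    return retained, flagged, results


def threshold_sweep(
    sites: Sequence[VariantSite],
    sheet: SampleSheet,
    thresholds: Sequence[int] | None = None,
) -> list[ThresholdSweepRow]:
    """Effect of the minimum-DH-heterozygote threshold on the flagged set.

    For each threshold k (default 1..n_DH) flags sites with dh_het_count >= k
    and summarises the flagged loci among the outbred samples: count, mean
    observed heterozygosity, and % with exact HWE p < 0.05. Rows are labelled
    both ways ("Het > k-1" and minimum count k); the final row, flagging only
    sites heterozygous in every DH line, is labelled "Het = n_DH".
    """
    n_dh = len(sheet.dh_indices)
    if thresholds is None:
        thresholds = list(range(1, n_dh + 1))
    outbred = sheet.non_dh_indices
    per_site = [
        (
            dh_het_count(s, sheet),
            observed_heterozygosity(s, outbred),
            outbred_hwe_p(s, sheet),
        )
        for s in sites
    ]
    rows: list[ThresholdSweepRow] = []
    for k in thresholds:
        flagged = [(ho, p) for cnt, ho, p in per_site if cnt >= k]
        n = len(flagged)
        hos = [ho for ho, _ in flagged if ho is not None]
        mean_ho = float(np.mean(hos)) if hos else 0.0
        n_dev = sum(1 for _, p in flagged if p < 0.05)
        label = f"Het = {n_dh}" if k == n_dh else f"Het > {k - 1}"
        rows.append(
            ThresholdSweepRow(
                label=label,
                min_het=k,
                n_flagged=n,
                mean_outbred_ho=mean_ho,
                pct_hwe_deviation=100.0 * n_dev / n if n else 0.0,
            )
        )
    return rows


def arm_density(
    flagged_sites: Iterable[VariantSite], build: GenomeBuild
) -> list[ArmDensity]:
    """Flagged-locus count per chromosome arm."""
    counts: dict[str, int] = {a.name: 0 for a in build.arms}
    for s in flagged_sites:
        arm = build.arm_of(s.chrom, s.pos)
        if arm is not None:
            counts[arm.name] += 1
    dup = build.duplicated_arm_names
    return [
        ArmDensity(
            arm=a.name,
            length=a.length,
            n_flagged=counts[a.name],
            is_delayed_rediploidization=a.name in dup,
        )
        for a in build.arms
    ]
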