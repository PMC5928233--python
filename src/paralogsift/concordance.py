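"""Two-caller concordance: per-site classification and summary accounting.

A SNP database built from two independent variant callers treats sites called
by both programs at the same position with the same alternate allele as its
trusted core. Each position present in either call set is classified as
unique to one caller, shared with the same ALT, or shared with a different
ALT. Two summary percentages are reported:

* same-ALT share of the combined set
  (denominator: unique_A + unique_B + same_alt + diff_alt);
* different-ALT share of the shared sites
  (denominator: same_alt + diff_alt).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import Genotype, SampleSheet, VariantSite
from .rounding import round_half_even


class ConcordanceCategory(enum.Enum):
    A_ONLY = "A_only"
    B_ONLY = "B_only"
    SAME_SITE_SAME_ALT = "same_site_same_alt"
    SAME_SITE_DIFF_ALT = "same_site_diff_alt"


@dataclass(frozen=True)
class ConcordanceRecord:
    chrom: str
    pos: int
    category: ConcordanceCategory
    alt_a: str | None = None
    alt_b: str | None = None

    def __post_init__(self) -> None:
        if self.category is ConcordanceCategory.A_ONLY and self.alt_b is not None:
            raise ValueError("A_only record must not carry alt_b")
        if self.category is ConcordanceCategory.B_ONLY and self.alt_a is not None:
            raise ValueError("B_only record must not carry alt_a")
        if (
            self.category is ConcordanceCategory.SAME_SITE_SAME_ALT
            and self.alt_a != self.alt_b
        ):
            raise ValueError("same_site_same_alt record must have alt_a == alt_b")


@dataclass
class ConcordanceSummary:
    n_a_only: int
    n_b_only: int
    n_same_alt: int
    n_diff_alt: int

    @property
    def n_combined(self) -> int:
        return self.n_a_only + self.n_b_only + self.n_same_alt + self.n_diff_alt

    @property
    def n_shared(self) -> int:
        return self.n_same_alt + self.n_diff_alt

    @property
    def pct_same_alt_of_combined(self) -> float:
        """Same-ALT percentage of the combined call sets, integer precision."""
        if self.n_combined == 0:
            return 0.0
        return round_half_even(100.0 * self.n_same_alt / self.n_combined, 0)

    @property
    def pct_diff_alt_of_shared(self) -> float:
        """Different-ALT percentage of shared sites, three-decimal precision."""
        if self.n_shared == 0:
            return 0.0
        return round_half_even(100.0 * self.n_diff_alt / self.n_shared, 3)


def _check_sorted(sites: Sequence[VariantSite], label: str) -> None:
    order: dict[str, int] = {}
    prev: tuple[int, int] | None = None
    for s in sites:
        order.setdefault(s.chrom, len(order))
        key = (order[s.chrom], s.pos)
        if prev is not None and key < prev:
            raise ValueError(f"call set {label} is not sorted at {s.chrom}:{s.pos}")
        prev = key


def classify_sites(
    callset_a: Iterable[VariantSite], callset_b: Iterable[VariantSite]
) -> list[ConcordanceRecord]:
    """Classify every position present in either (sorted, bi-allelic SNP)
    call set.

    Sites are keyed by (chrom, pos) only: a REF mismatch at a shared position
    is folded into same_site_diff_alt, since both callers share one reference
    and a mismatch reflects representation differences.
    """
    a = list(callset_a)
    b = list(callset_b)
    _check_sorted(a, "A")
    _check_sorted(b, "B")
    b_by_key = {s.key: s for s in b}
    a_keys = {s.key for s in a}
    records: list[ConcordanceRecord] = []
    for s in a:
        alt_a = s.alt_alleles[0]
        other = b_by_key.get(s.key)
        if other is None:
            records.append(
                ConcordanceRecord(s.chrom, s.pos, ConcordanceCategory.A_ONLY, alt_a=alt_a)
            )
        else:
            alt_b = other.alt_alleles[0]
            same = alt_a == alt_b and s.ref_allele == other.ref_allele
            cat = (
                ConcordanceCategory.SAME_SITE_SAME_ALT
                if same
                else ConcordanceCategory.SAME_SITE_DIFF_ALT
            )
            records.append(ConcordanceRecord(s.chrom, s.pos, cat, alt_a=alt_a, alt_b=alt_b))
    for s in b:
        if s.key not in a_keys:
            records.append(
                ConcordanceRecord(
                    s.chrom, s.pos, ConcordanceCategory.B_ONLY, alt_b=s.alt_alleles[0]
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def concordance_summary(records: Iterable[ConcordanceRecord]) -> ConcordanceSummary:
    counts = {c: 0 for c in ConcordanceCategory}
    for r in records:
        counts[r.category] += 1
    return ConcordanceSummary(
        n_a_only=counts[ConcordanceCategory.A_ONLY],
        n_b_only=counts[ConcordanceCategory.B_ONLY],
        n_same_alt=counts[ConcordanceCategory.SAME_SITE_SAME_ALT],
        n_diff_alt=counts[ConcordanceCategory.SAME_SITE_DIFF_ALT],
    )


def intersect_same_alt(
    callset_a: Sequence[VariantSite], records: Iterable[ConcordanceRecord]
) -> list[VariantSite]:
    """The trusted core: caller-A records at same-site-same-ALT positions."""
    keep = {
        (r.chrom, r.pos)
        for r in records
        if r.category is ConcordanceCategory.SAME_SITE_SAME_ALT
    }
    return [s for s in callset_a if s.key in keep]


def missingness_accumulation(
    sites_by_caller: dict[str, Sequence[VariantSite]],
    sheet: SampleSheet,
    ns_levels: Sequence[int],
) -> dict[int, dict[str, int]]:
    """Sites per callable-sample count, per caller and for their same-ALT
    intersection.

    For each level n in ``ns_levels`` counts the sites whose number of
    non-missing genotypes equals n exactly. Requires exactly two callers.
    """
    if len(sites_by_caller) != 2:
        raise ValueError("missingness accumulation requires exactly two call sets")

    def n_callable(site: VariantSite) -> int:
        return sum(1 for c in site.per_sample if c.genotype is not Genotype.MISSING)

    (name_a, a), (name_b, b) = sites_by_caller.items()
    records = classify_sites(sorted(a, key=lambda s: (s.chrom, s.pos)),
                             sorted(b, key=lambda s: (s.chrom, s.pos)))
    shared = {
        (r.chrom, r.pos)
        for r in records
        if r.category is ConcordanceCategory.SAME_SITE_SAME_ALT
    }
    out: dict[int, dict[str, int]] = {n: {name_a: 0, name_b: 0, "both": 0} for n in ns_levels}
    level_set = set(ns_levels)
    callable_a: dict[tuple[str, int], int] = {}
    for s in a:
        n = n_callable(s)
        callable_a[s.key] = n
        if n in level_set:
            out[n][name_a] += 1
    for s in b:
        n = n_callable(s)
        if n in level_set:
            out[n][name_b] += 1
        # intersection callability: a site counts at the level both callers
        # support; the stricter (smaller) callable count is used
        if s.key in shared:
            n_joint = min(n, callable_a[s.key])
            if n_joint in level_set:
                out[n_joint]["both"] += 1
    return out
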