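"""The five-stage SNP filter cascade and the per-sample genotype-calling rule.

Stages, applied in order with per-stage accounting:

QUAL  keep bi-allelic SNPs with phred quality strictly above 30 that are not
      within 4 bp of an indel (indels themselves are removed here);
LC    drop SNPs inside low-complexity regions (DUST-style trinucleotide
      score, window 64);
DP    drop sites whose summed read depth across samples exceeds 1,500 —
      excess depth marks collapsed repeats;
NS    re-call genotypes from allelic depths (het requires >=2 alternate and
      >=1 reference read) and keep sites callable in at least 58 of 61
      samples (ceil(0.95*N) for other panel sizes).

The fifth stage — the doubled-haploid heterozygosity screen — lives in
:mod:`paralogsift.duplication`.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import Genotype, MaskRegion, SampleCall, SampleSheet, VariantSite
from .vcf_io import merge_regions

STAGES = ("QUAL", "LC", "DP", "NS")


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade.

    min_qual: QUAL must be strictly larger than this (phred scale).
    indel_distance: SNPs within this many bases of an indel anchor are dropped.
    max_depth: maximum summed read depth over all samples.
    min_samples: minimum callable samples; None means ceil(0.95 * N).
    min_alt_reads / min_ref_reads: the genotype-calling read-support rule.
    dust_window / dust_threshold: low-complexity scoring window and cutoff.
    recall_genotypes: re-derive GT from allelic depths (default) rather than
        trusting the caller's GT field.
    """

    min_qual: float = 30.0
    indel_distance: int = 4
    max_depth: int = 1500
    min_samples: int | None = None
    min_alt_reads: int = 2
    min_ref_reads: int = 1
    dust_window: int = 64
    dust_threshold: float = 2.0
    recall_genotypes: bool = True

    def resolved_min_samples(self, n_samples: int) -> int:
        if self.min_samples is not None:
            return self.min_samples
        return math.ceil(0.95 * n_samples)


@dataclass
class FilterLedger:
    """Per-stage accounting: sites entering and passing each stage."""

    entering: dict[str, int] = field(default_factory=dict)
    passing: dict[str, int] = field(default_factory=dict)

    def record(self, stage: str, entering: int, passing: int) -> None:
        self.entering[stage] = entering
        self.passing[stage] = passing

    @property
    def removed(self) -> dict[str, int]:
        return {s: self.entering[s] - self.passing[s] for s in self.entering}

    def to_rows(self) -> list[tuple[str, int, int, int]]:
        return [
            (s, self.entering[s], self.passing[s], self.entering[s] - self.passing[s])
            for s in self.entering
        ]


# ---------------------------------------------------------------------------
# Stage predicates (pure, per-site)


def collect_indel_positions(sites: Iterable[VariantSite]) -> dict[str, list[int]]:
    """Sorted indel anchor positions per chromosome, from a raw call set."""
    out: dict[str, list[int]] = {}
    for s in sites:
        if s.is_indel:
            out.setdefault(s.chrom, []).append(s.pos)
    for chrom in out:
        out[chrom].sort()
    return out


def near_indel(
    site: VariantSite, indel_positions: dict[str, list[int]], distance: int
) -> bool:
    """True if an indel anchor lies within ``distance`` bases (|delta| <= d)."""
    positions = indel_positions.get(site.chrom)
    if not positions:
        return False
    i = bisect.bisect_left(positions, site.pos - distance)
    return i < len(positions) and positions[i] <= site.pos + distance


def filter_qual_biallelic(
    site: VariantSite,
    indel_positions: dict[str, list[int]],
    cfg: FilterConfig,
) -> tuple[bool, str | None]:
    """QUAL stage: bi-allelic SNP, QUAL strictly > min_qual, no nearby indel."""
    if not site.is_biallelic_snp:
        return False, "not_biallelic_snp"
    if not site.qual > cfg.min_qual:
        return False, "low_qual"
    if near_indel(site, indel_positions, cfg.indel_distance):
        return False, "near_indel"
    return True, None


def filter_low_complexity(
    site: VariantSite, masks: Sequence[MaskRegion]
) -> bool:
    """LC stage: fail iff the site position falls inside a mask region."""
    return not site_in_masks(site.chrom, site.pos, masks)


def site_in_masks(chrom: str, pos: int, masks: Sequence[MaskRegion]) -> bool:
    p0 = pos - 1  # VCF 1-based -> BED 0-based
    for r in masks:
        if r.chrom == chrom and r.start <= p0 < r.end:
            return True
    return False


class MaskIndex:
    """Sorted-interval index over merged mask regions for O(log n) lookup."""

    def __init__(self, masks: Iterable[MaskRegion]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for r in merge_regions(masks):
            self._starts.setdefault(r.chrom, []).append(r.start)
            self._ends.setdefault(r.chrom, []).append(r.end)

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        p0 = pos - 1
        i = bisect.bisect_right(starts, p0) - 1
        return i >= 0 and p0 < self._ends[chrom][i]


def filter_max_depth(site: VariantSite, cfg: FilterConfig) -> bool:
    """DP stage: fail iff summed reads over samples exceed max_depth."""
    return site.total_depth() <= cfg.max_depth


def call_genotype(call: SampleCall, cfg: FilterConfig) -> Genotype:
    """Genotype from allelic depths.

    het requires >= min_alt_reads alternate and >= min_ref_reads reference
    reads; homozygotes require >= min_alt_reads of the observed allele and
    zero of the other; anything else is missing.
    """
    r, a = call.ref_reads, call.alt_reads
    if r is None or a is None:
        return call.genotype  # no AD: keep the caller's GT
    if a >= cfg.min_alt_reads and r >= cfg.min_ref_reads:
        return Genotype.HET
    if a >= cfg.min_alt_reads and r == 0:
        return Genotype.HOM_ALT
    if r >= cfg.min_alt_reads and a == 0:
        return Genotype.HOM_REF
    return Genotype.MISSING


def recall_genotypes(site: VariantSite, cfg: FilterConfig) -> None:
    for c in site.per_sample:
        c.genotype = call_genotype(c, cfg)


def filter_min_samples(site: VariantSite, cfg: FilterConfig) -> bool:
    """NS stage: pass iff callable (non-missing) genotypes >= min_samples."""
    n_called = sum(1 for c in site.per_sample if c.genotype is not Genotype.MISSING)
    return n_called >= cfg.resolved_min_samples(len(site.per_sample))


# ---------------------------------------------------------------------------
# Low-complexity masking (DUST-style)


def dust_mask(sequence: str, cfg: FilterConfig | None = None) -> list[MaskRegion]:
    """DUST-style low-complexity mask of one chromosome sequence.

    A window of ``dust_window`` bases scores sum_i c_i*(c_i-1)/2 over its
    trinucleotide counts c_i, normalised by (window-3); windows scoring
    strictly above ``dust_threshold`` are masked and overlapping masked
    windows merged. Runs of N are always masked. The returned regions are
    0-based half-open on the chromosome named "" (callers re-attach the name).
    """
    cfg = cfg or FilterConfig()
    w = cfg.dust_window
    if w < 3:
        raise ValueError("dust window must be at least 3 bases")
    seq = sequence.upper()
    n = len(seq)
    intervals: list[tuple[int, int]] = []

    # N runs: always masked, and they split the scan into clean segments
    seg_start = 0
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            if i > seg_start:
                segments.append((seg_start, i))
            intervals.append((i, j))
            seg_start = j
            i = j
        else:
            i += 1
    if n > seg_start:
        segments.append((seg_start, n))

    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for s0, s1 in segments:
        L = s1 - s0
        if L < 3:
            continue
        win = min(w, L)
        norm = max(win - 3, 1)
        # trinucleotide ids for the segment
        trip = []
        for k in range(s0, s1 - 2):
            trip.append(
                code[seq[k]] * 16 + code[seq[k + 1]] * 4 + code[seq[k + 2]]
            )
        counts = [0] * 64
        score2 = 0  # 2 * sum c_i*(c_i-1)/2 = sum c_i*(c_i-1)
        ntrip_win = win - 2
        for k, t in enumerate(trip[:ntrip_win]):
            score2 += 2 * counts[t]
            counts[t] += 1
        masked_from: int | None = None
        last_end = 0
        for start in range(0, len(trip) - ntrip_win + 1):
            if start > 0:
                t_out = trip[start - 1]
                counts[t_out] -= 1
                score2 -= 2 * counts[t_out]
                t_in = trip[start + ntrip_win - 1]
                score2 += 2 * counts[t_in]
                counts[t_in] += 1
            if (score2 / 2) / norm > cfg.dust_threshold:
                w_s, w_e = s0 + start, s0 + start + win
                if masked_from is None:
                    masked_from, last_end = w_s, w_e
                else:
                    last_end = w_e
            elif masked_from is not None:
                intervals.append((masked_from, last_end))
                masked_from = None
        if masked_from is not None:
            intervals.append((masked_from, last_end))
        counts = [0] * 64  # reset guard (recomputed per segment anyway)

    regions = [MaskRegion("", s, e) for s, e in intervals]
    return merge_regions(regions) if regions else []


def dust_mask_genome(
    seqs: dict[str, str], cfg: FilterConfig | None = None
) -> list[MaskRegion]:
    out: list[MaskRegion] = []
    for chrom, seq in seqs.items():
        out.extend(MaskRegion(chrom, r.start, r.end) for r in dust_mask(seq, cfg))
    return out


# ---------------------------------------------------------------------------
# The cascade


def apply_filter_cascade(
    sites: Iterable[VariantSite],
    masks: Iterable[MaskRegion],
    cfg: FilterConfig,
    sheet: SampleSheet,
) -> tuple[list[VariantSite], FilterLedger]:
    """Apply QUAL -> LC -> DP -> NS in order with per-stage accounting.

    Genotypes are (re-)called from allelic depths before the NS stage unless
    ``cfg.recall_genotypes`` is False. Survivors carry called genotypes for
    the downstream doubled-haploid screen and statistics.
    """
    sites = list(sites)
    ledger = FilterLedger()
    mask_index = MaskIndex(masks)
    indels = collect_indel_positions(sites)

    entering = sites
    passing = [s for s in entering if filter_qual_biallelic(s, indels, cfg)[0]]
    ledger.record("QUAL", len(entering), len(passing))

    entering = passing
    passing = [s for s in entering if not mask_index.contains(s.chrom, s.pos)]
    ledger.record("LC", len(entering), len(passing))

    entering = passing
    passing = [s for s in entering if filter_max_depth(s, cfg)]
    ledger.record("DP", len(entering), len(passing))

    entering = passing
    if cfg.recall_genotypes:
        for s in entering:
            recall_genotypes(s, cfg)
    passing = [s for s in entering if filter_min_samples(s, cfg)]
    ledger.record("NS", len(entering), len(passing))

    return passing, ledger
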