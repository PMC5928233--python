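"""Database characterisation: MAF spectrum, per-population polymorphism,
windowed nucleotide diversity, and SNP density by chromosome.

All statistics operate on the called-genotype matrix of the filtered site
set. Allele frequencies count two alleles per called sample (61 samples fully
called give 122 alleles per SNP); nucleotide diversity uses the unbiased
per-site estimator pi_site = (n/(n-1)) * 2p(1-p), accumulated in fixed
genomic windows and divided by the true window width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import GenomeBuild, Genotype, SampleSheet, VariantSite
from .rounding import mean2, pct_int, round_half_even

_GT_CODE = {
    Genotype.HOM_REF: 0,
    Genotype.HET: 1,
    Genotype.HOM_ALT: 2,
    Genotype.MISSING: -1,
}


def genotype_matrix(sites: Sequence[VariantSite]) -> np.ndarray:
    """Sites x samples matrix of alt-allele dosage (0/1/2, -1 missing)."""
    mat = np.empty((len(sites), len(sites[0].per_sample) if sites else 0), dtype=np.int8)
    for i, s in enumerate(sites):
        for j, c in enumerate(s.per_sample):
            mat[i, j] = _GT_CODE[c.genotype]
    return mat


@dataclass
class PopPolymorphismRow:
    population: str
    n_fish: int
    n_sites_full_data: int
    n_polymorphic: int
    pct_polymorphic: float
    mean_maf_polymorphic: float
    mean_ho_polymorphic: float


@dataclass
class DensityRow:
    chrom: str
    length: int
    n_snps: int

    @property
    def rate_bp(self) -> int:
        """Average spacing in bases per SNP; truncated, not rounded."""
        return self.length // self.n_snps if self.n_snps else 0


@dataclass
class PiWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    pi: float  # per-bp nucleotide diversity in this window


def minor_allele_frequency(
    site: VariantSite, indices: Sequence[int] | None = None
) -> float | None:
    """MAF over two alleles per called sample in the subset (None if no
    calls)."""
    if indices is None:
        indices = range(len(site.per_sample))
    n_called = alt = 0
    for i in indices:
        g = site.per_sample[i].genotype
        if g is Genotype.MISSING:
            continue
        n_called += 1
        alt += _GT_CODE[g]
    if n_called == 0:
        return None
    f = alt / (2 * n_called)
    return min(f, 1.0 - f)


def maf_spectrum(
    sites: Iterable[VariantSite],
    bin_edges: Sequence[float] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50),
    indices: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """MAF histogram over all samples (DH lines included).

    Returns (counts per bin, proportions, proportion of sites with
    MAF < 0.05). Bins are half-open [lo, hi) except the last, which is
    closed at 0.5.
    """
    mafs = [minor_allele_frequency(s, indices) for s in sites]
    mafs = np.array([m for m in mafs if m is not None])
    edges = np.asarray(bin_edges, dtype=float)
    if mafs.size == 0:
        return np.zeros(len(edges) - 1, dtype=int), np.zeros(len(edges) - 1), 0.0
    counts, _ = np.histogram(mafs, bins=edges)
    props = counts / counts.sum()
    prop_rare = float((mafs < 0.05).mean())
    return counts, props, prop_rare


def population_polymorphism(
    sites: Sequence[VariantSite], sheet: SampleSheet, dh_group_label: str = "DH"
) -> list[PopPolymorphismRow]:
    """Per-population polymorphism survey, plus one row pooling the DH lines.

    Restricted per population to sites with a called genotype for every fish
    in that population; polymorphic means both alleles observed among those
    genotypes. Percentages print at integer precision, means at two decimals.
    """
    groups: dict[str, list[int]] = {
        pop: idx
        for pop, idx in sheet.populations.items()
        if not any(sheet.entries[i].is_dh for i in idx)
    }
    if sheet.dh_indices:
        groups[dh_group_label] = sheet.dh_indices
    mat = (
        genotype_matrix(sites)
        if sites
        else np.empty((0, len(sheet)), dtype=np.int8)
    )
    rows: list[PopPolymorphismRow] = []
    for pop, idx in groups.items():
        sub = mat[:, idx]
        full = (sub >= 0).all(axis=1)
        n_full = int(full.sum())
        sub_full = sub[full]
        alt = sub_full.sum(axis=1)
        n_alleles = 2 * len(idx)
        poly = (alt > 0) & (alt < n_alleles)
        n_poly = int(poly.sum())
        if n_poly:
            f = alt[poly] / n_alleles
            maf = np.minimum(f, 1.0 - f)
            ho = (sub_full[poly] == 1).mean(axis=1)
            mean_maf, mean_ho = float(maf.mean()), float(ho.mean())
        else:
            mean_maf = mean_ho = 0.0
        rows.append(
            PopPolymorphismRow(
                population=pop,
                n_fish=len(idx),
                n_sites_full_data=n_full,
                n_polymorphic=n_poly,
                pct_polymorphic=pct_int(n_poly, n_full),
                mean_maf_polymorphic=mean2(mean_maf),
                mean_ho_polymorphic=mean2(mean_ho),
            )
        )
    return rows


def site_pi(site: VariantSite, indices: Sequence[int] | None = None) -> float:
    """Unbiased per-site diversity (n/(n-1)) * 2p(1-p) over called alleles."""
    if indices is None:
        indices = range(len(site.per_sample))
    n_called = alt = 0
    for i in indices:
        g = site.per_sample[i].genotype
        if g is Genotype.MISSING:
            continue
        n_called += 1
        alt += _GT_CODE[g]
    n = 2 * n_called
    if n < 2:
        return 0.0
    p = alt / n
    return (n / (n - 1)) * 2.0 * p * (1.0 - p)


def nucleotide_diversity_windows(
    sites: Sequence[VariantSite],
    build: GenomeBuild,
    window: int = 20_000,
    indices: Sequence[int] | None = None,
) -> tuple[list[PiWindow], float]:
    """Windowed nucleotide diversity and its genome-wide mean.

    Every window of every chromosome in the build is emitted (zero where no
    SNPs fall); trailing partial windows are normalised by their true width.
    The genome mean is the unweighted mean over windows.
    """
    sums: dict[tuple[str, int], float] = {}
    for s in sites:
        if s.chrom not in build.chrom_lengths:
            continue
        w = (s.pos - 1) // window
        sums[(s.chrom, w)] = sums.get((s.chrom, w), 0.0) + site_pi(s, indices)
    windows: list[PiWindow] = []
    for chrom, length in build.chrom_lengths.items():
        n_win = (length + window - 1) // window
        for w in range(n_win):
            start = w * window
            end = min(start + window, length)
            total = sums.get((chrom, w), 0.0)
            windows.append(PiWindow(chrom, start, end, total / (end - start)))
    mean_pi = float(np.mean([w.pi for w in windows])) if windows else 0.0
    return windows, mean_pi


def snp_density_table(
    sites: Iterable[VariantSite], build: GenomeBuild
) -> tuple[list[DensityRow], DensityRow]:
    """SNP count and truncated average spacing per chromosome, with unplaced
    scaffolds aggregated into one row; the genome-wide row covers the
    chromosomes only."""
    counts: dict[str, int] = {c: 0 for c in build.chrom_lengths}
    n_unplaced = 0
    for s in sites:
        if s.chrom in counts:
            counts[s.chrom] += 1
        elif s.chrom in build.unplaced:
            n_unplaced += 1
    rows = [DensityRow(c, l, counts[c]) for c, l in build.chrom_lengths.items()]
    if build.unplaced:
        rows.append(
            DensityRow("unplaced", sum(build.unplaced.values()), n_unplaced)
        )
    genome = DensityRow(
        "all_chromosomes",
        build.total_chrom_length,
        sum(counts.values()),
    )
    return rows, genome


def snps_per_kb(genome_row: DensityRow) -> float:
    """Genome-wide SNP density per kb at one-decimal precision."""
    if genome_row.length == 0:
        return 0.0
    return round_half_even(1000.0 * genome_row.n_snps / genome_row.length, 1)
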