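"""Core domain types shared by every stage of the pipeline.

The in-memory representation is deliberately small: a variant site carries its
coordinates, alleles, quality and per-sample read support; everything else
(filter verdicts, screen classifications) is attached as plain info flags or
returned as separate records. Coordinates follow the VCF convention (1-based
positions); mask regions follow BED (0-based half-open).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass
class SampleCall:
    """Read support and genotype for one sample at one site.

    ``ref_reads``/``alt_reads`` are allelic depths (the VCF AD field); a value
    of ``None`` means the call set carried no per-allele depth, in which case
    depth-dependent filters fall back to ``depth``.
    """

    ref_reads: int | None = None
    alt_reads: int | None = None
    genotype: Genotype = Genotype.MISSING
    depth: int | None = None

    def total_depth(self) -> int:
        if self.ref_reads is not None and self.alt_reads is not None:
            return self.ref_reads + self.alt_reads
        return self.depth or 0


@dataclass
class VariantSite:
    """One candidate variant: a VCF record restricted to the fields the
    pipeline uses (CHROM, POS, REF, ALT, QUAL, per-sample GT:AD:DP)."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: list[str]
    qual: float
    per_sample: list[SampleCall]
    info_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if self.qual < 0:
            raise ValueError(f"QUAL must be >= 0, got {self.qual}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and all(
            len(a) == 1 for a in self.alt_alleles
        )

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != 1 or any(len(a) != 1 for a in self.alt_alleles)

    @property
    def is_biallelic_snp(self) -> bool:
        return len(self.alt_alleles) == 1 and self.is_snp

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def total_depth(self) -> int:
        return sum(c.total_depth() for c in self.per_sample)


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    population: str
    is_dh: bool


class SampleSheet:
    """Ordered sample metadata: id, population label, doubled-haploid flag.

    The entry order defines the per-sample column order everywhere in the
    pipeline.
    """

    def __init__(self, entries: Iterable[SampleEntry]):
        self.entries: list[SampleEntry] = list(entries)
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in sample sheet")
        self._index = {e.sample_id: i for i, e in enumerate(self.entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def dh_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e.is_dh]

    @property
    def non_dh_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if not e.is_dh]

    @property
    def populations(self) -> dict[str, list[int]]:
        """Population label -> sample indices, in first-seen order."""
        pops: dict[str, list[int]] = {}
        for i, e in enumerate(self.entries):
            pops.setdefault(e.population, []).append(i)
        return pops

    def index_of(self, sample_id: str) -> int:
        return self._index[sample_id]


@dataclass(frozen=True)
class MaskRegion:
    """A low-complexity (or otherwise masked) interval, BED-style 0-based
    half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"mask region must have start < end, got [{self.start},{self.end})"
            )

    def contains_pos(self, pos: int) -> bool:
        """Whether a 1-based VCF position falls inside this region."""
        return self.start <= pos - 1 < self.end


@dataclass
class Arm:
    name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeBuild:
    """Chromosome names/lengths, arm boundaries and duplicated arm pairs.

    When no arm table is supplied each chromosome is treated as a single arm
    (named after the chromosome).
    """

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        arms: Sequence[Arm] | None = None,
        duplicated_pairs: Sequence[tuple[str, str]] = (),
        unplaced: Mapping[str, int] | None = None,
    ):
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        if arms is None:
            arms = [Arm(name=c, chrom=c, start=0, end=l) for c, l in self.chrom_lengths.items()]
        self.arms: list[Arm] = list(arms)
        self.duplicated_pairs: list[tuple[str, str]] = [tuple(p) for p in duplicated_pairs]
        self.unplaced: dict[str, int] = dict(unplaced or {})
        self._arms_by_chrom: dict[str, list[Arm]] = {}
        for a in self.arms:
            self._arms_by_chrom.setdefault(a.chrom, []).append(a)
        for lst in self._arms_by_chrom.values():
            lst.sort(key=lambda a: a.start)

    @property
    def duplicated_arm_names(self) -> set[str]:
        return {n for pair in self.duplicated_pairs for n in pair}

    def arm_of(self, chrom: str, pos: int) -> Arm | None:
        """Arm containing a 1-based position, or None."""
        for a in self._arms_by_chrom.get(chrom, []):
            if a.start <= pos - 1 < a.end:
                return a
        return None

    @property
    def total_chrom_length(self) -> int:
        return sum(self.chrom_lengths.values())
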