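"""Synthetic study generator: genome, samples, planted variants, two callers.

Everything the pipeline consumes is generated here with the statistical
structure the analysis assumes, at desk scale:

* a genome of a few chromosomes split into p/q arms, where designated arm
  pairs are near-identical copies (delayed rediploidization after whole
  genome duplication), plus embedded low-complexity tracts and indels;
* a 61-sample panel — 11 doubled-haploid (DH) lines, a 12-fish aquaculture
  population, seven populations of four fish and a handful of small
  populations — mirroring the resequencing design the pipeline targets;
* planted variants with per-site truth: true SNPs (Balding–Nichols
  population frequencies around a Beta-distributed ancestral frequency),
  PSVs (fixed differences between collapsed paralogs: every sample sees a
  ~50/50 read mixture) and MSVs (variants segregating on one collapsed
  paralog copy: quarter-dose read mixtures);
* per-sample allelic read depths (Poisson depth at a per-sample mean drawn
  between the minimum and ~2x-mean coverage, binomial allele sampling,
  small base-error rate);
* two discordant caller outputs: each caller misses an independent fraction
  of sites (derived in closed form from the configured target concordance),
  adds unique false sites, disagrees on ALT at a small rate, and draws its
  own QUAL with a configured sub-threshold fraction.

A fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import (
    Arm,
    GenomeBuild,
    Genotype,
    MaskRegion,
    SampleCall,
    SampleEntry,
    SampleSheet,
    VariantSite,
)
from .vcf_io import write_bed, write_fasta, write_sample_sheet, write_vcf

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Densities are per base pair, rates are probabilities. The defaults
    emulate the target study: 61 samples (11 DH lines) at 15X mean / 8X
    minimum coverage, ~80% two-caller same-site-same-ALT concordance, and a
    small genome (2 chromosomes x 2 arms of 120 kb) with one duplicated arm
    pair carrying elevated PSV/MSV density.
    """

    seed: int = 0
    n_chromosomes: int = 2
    arm_length: int = 120_000
    duplicated_pairs: tuple[tuple[str, str], ...] = (("chr1q", "chr2p"),)
    paralog_divergence: float = 0.002

    snp_density: float = 0.008
    psv_density: float = 0.0015
    msv_density: float = 0.0008
    maf_beta: tuple[float, float] = (0.5, 0.5)
    msv_beta: tuple[float, float] = (2.0, 2.0)
    fst: float = 0.1

    psv_site_bias_beta: tuple[float, float] = (8.0, 8.0)
    psv_read_concentration: float = 40.0

    n_dh: int = 11
    residual_dh_het: float = 0.005
    mean_coverage: float = 15.0
    min_coverage: float = 8.0
    base_error_rate: float = 0.0005

    qual_low_rate: float = 0.05
    target_concordance: float = 0.80
    caller_unique_false_rate: float = 0.01
    alt_disagreement_rate: float = 0.0004
    high_depth_site_rate: float = 0.002

    lc_tract_density: float = 0.0003
    lc_tract_length: tuple[int, int] = (100, 400)
    indel_density: float = 0.00002

    def artifact_free(self) -> "SimConfig":
        """A copy with no planted artifacts (clean-cascade property runs)."""
        return dataclasses.replace(
            self,
            qual_low_rate=0.0,
            high_depth_site_rate=0.0,
            lc_tract_density=0.0,
            indel_density=0.0,
        )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulator config keys: {sorted(unknown)}")
        for key in ("duplicated_pairs",):
            if key in raw:
                raw[key] = tuple(tuple(p) for p in raw[key])
        for key in ("maf_beta", "msv_beta", "psv_site_bias_beta", "lc_tract_length"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# Outbred population design: label -> number of fish (Table-5-like shape)
OUTBRED_POPULATIONS: dict[str, int] = {
    "Dworshak": 4,
    "Quinault": 4,
    "LQuinault": 4,
    "Elwha": 4,
    "Skamania": 4,
    "BigCreek": 4,
    "Klamath": 4,
    "Aquagen": 12,
    "Other1": 2,
    "Other2": 2,
    "Other3": 2,
    "Other4": 2,
    "Other5": 2,
}
DH_POPULATION = "DHline"


def build_sample_sheet(cfg: SimConfig) -> SampleSheet:
    entries = []
    for pop, n in OUTBRED_POPULATIONS.items():
        for k in range(1, n + 1):
            entries.append(SampleEntry(f"{pop}_{k:02d}", pop, False))
    for k in range(1, cfg.n_dh + 1):
        entries.append(SampleEntry(f"DH_{k:02d}", DH_POPULATION, True))
    return SampleSheet(entries)


@dataclass
class TruthVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    cls: str  # true_snp | psv | msv | artifact
    ancestral_freq: float
    dosages: np.ndarray  # per-sample true alt dosage (true_snp/msv: 0/1/2; psv: 1)
    high_depth: bool = False


class TruthTable:
    def __init__(self, variants: list[TruthVariant], sheet: SampleSheet):
        self.variants = variants
        self.sheet = sheet
        self.by_key = {(v.chrom, v.pos): v for v in variants}

    def keys_of_class(self, *classes: str) -> set[tuple[str, int]]:
        return {(v.chrom, v.pos) for v in self.variants if v.cls in classes}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\tclass\tancestral_freq\thigh_depth\tdosages\n")
            for v in self.variants:
                dos = "".join(str(int(d)) for d in v.dosages)
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.cls}\t"
                    f"{v.ancestral_freq:.6f}\t{int(v.high_depth)}\t{dos}\n"
                )

    @classmethod
    def read_tsv(cls, path, sheet: SampleSheet) -> "TruthTable":
        variants = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                c, p, r, a, k, f, hd, dos = line.rstrip("\n").split("\t")
                variants.append(
                    TruthVariant(
                        c, int(p), r, a, k, float(f),
                        np.array([int(x) for x in dos], dtype=np.int8),
                        bool(int(hd)),
                    )
                )
        return cls(variants, sheet)


@dataclass
class SimResult:
    cfg: SimConfig
    sequences: dict[str, str]
    build: GenomeBuild
    sheet: SampleSheet
    truth: TruthTable
    callset_a: list[VariantSite]
    callset_b: list[VariantSite]
    lc_tracts: list[MaskRegion]
    indel_positions: dict[str, list[int]]

    def write(self, outdir) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": out / "reference.fa",
            "truth": out / "truth.tsv",
            "caller_a": out / "callerA.vcf",
            "caller_b": out / "callerB.vcf",
            "samples": out / "samples.tsv",
            "arms": out / "arms.tsv",
            "lc_tracts": out / "lc_tracts.bed",
            "genes": out / "genes.gff3",
        }
        write_fasta(self.sequences, paths["reference"])
        self.truth.write_tsv(paths["truth"])
        lengths = self.build.chrom_lengths
        write_vcf(self.callset_a, self.sheet, paths["caller_a"], contig_lengths=lengths)
        write_vcf(self.callset_b, self.sheet, paths["caller_b"], contig_lengths=lengths)
        write_sample_sheet(self.sheet, paths["samples"])
        write_arm_table(self.build, paths["arms"])
        if self.lc_tracts:
            write_bed(self.lc_tracts, paths["lc_tracts"])
        else:
            paths["lc_tracts"].write_text("")
        write_toy_gff3(self.build, self.sequences, paths["genes"])
        return paths


def write_arm_table(build: GenomeBuild, path) -> None:
    dup = build.duplicated_arm_names
    with open(path, "w") as fh:
        fh.write("#arm\tchrom\tstart\tend\tduplicated\n")
        for a in build.arms:
            fh.write(f"{a.name}\t{a.chrom}\t{a.start}\t{a.end}\t{int(a.name in dup)}\n")


def read_arm_table(path) -> tuple[list[Arm], list[tuple[str, str]]]:
    arms: list[Arm] = []
    dup_names: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, chrom, s, e, d = line.rstrip("\n").split("\t")
            arms.append(Arm(name, chrom, int(s), int(e)))
            if d == "1":
                dup_names.append(name)
    # pair duplicated arms in listed order
    pairs = [tuple(dup_names[i : i + 2]) for i in range(0, len(dup_names) - 1, 2)]
    return arms, pairs


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], GenomeBuild, list[MaskRegion], dict[str, list[int]]]:
    """Reference sequences, build (arms + duplicated pairs), embedded
    low-complexity tracts, and indel positions."""
    chrom_len = 2 * cfg.arm_length
    names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    arrs: dict[str, np.ndarray] = {
        n: rng.integers(0, 4, size=chrom_len) for n in names
    }
    arms: list[Arm] = []
    for n in names:
        arms.append(Arm(f"{n}p", n, 0, cfg.arm_length))
        arms.append(Arm(f"{n}q", n, cfg.arm_length, chrom_len))
    arm_by_name = {a.name: a for a in arms}

    # low-complexity tracts: homopolymer or dinucleotide repeats. Tracts are
    # kept off the destination arms of duplicated pairs; the copy step below
    # mirrors source-arm tracts onto the destination so the shared repeats of
    # a duplicated pair appear on both copies and the tract record is exact.
    dest_arms = [arm_by_name[b] for _, b in cfg.duplicated_pairs]
    tracts: list[MaskRegion] = []
    for n in names:
        n_tracts = rng.poisson(cfg.lc_tract_density * chrom_len)
        placed = 0
        while placed < n_tracts:
            length = int(rng.integers(cfg.lc_tract_length[0], cfg.lc_tract_length[1] + 1))
            start = int(rng.integers(0, chrom_len - length))
            if any(
                d.chrom == n and start < d.end and d.start < start + length
                for d in dest_arms
            ):
                continue
            if rng.random() < 0.5:
                unit = [int(rng.integers(0, 4))]
            else:
                b1 = int(rng.integers(0, 4))
                b2 = (b1 + 1 + int(rng.integers(0, 3))) % 4
                unit = [b1, b2]
            rep = np.tile(np.array(unit), length // len(unit) + 1)[:length]
            arrs[n][start : start + length] = rep
            tracts.append(MaskRegion(n, start, start + length))
            placed += 1

    # duplicated arm pairs: second member is a diverged copy of the first
    for a_name, b_name in cfg.duplicated_pairs:
        a, b = arm_by_name[a_name], arm_by_name[b_name]
        src = arrs[a.chrom][a.start : a.end].copy()
        n_div = rng.poisson(cfg.paralog_divergence * len(src))
        div_pos = rng.choice(len(src), size=min(n_div, len(src)), replace=False)
        src[div_pos] = (src[div_pos] + 1 + rng.integers(0, 3, size=len(div_pos))) % 4
        arrs[b.chrom][b.start : b.end] = src
        for t in [t for t in tracts if t.chrom == a.chrom and t.start < a.end and a.start < t.end]:
            lo, hi = max(t.start, a.start), min(t.end, a.end)
            tracts.append(
                MaskRegion(b.chrom, b.start + (lo - a.start), b.start + (hi - a.start))
            )

    indels: dict[str, list[int]] = {}
    for n in names:
        n_ind = rng.poisson(cfg.indel_density * chrom_len)
        pos = sorted(int(p) + 1 for p in rng.choice(chrom_len - 1, size=n_ind, replace=False))
        indels[n] = pos

    seqs = {n: "".join(BASES[arrs[n]]) for n in names}
    build = GenomeBuild(
        {n: chrom_len for n in names}, arms, list(cfg.duplicated_pairs)
    )
    return seqs, build, tracts, indels


# ---------------------------------------------------------------------------
# Variants and samples


def _balding_nichols(
    p0: float, fst: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-population frequencies around ancestral p0 at divergence fst."""
    if fst <= 0:
        return np.full(n, p0)
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    return rng.beta(max(a, 1e-6), max(b, 1e-6), size=n)


def plant_variants(
    cfg: SimConfig,
    build: GenomeBuild,
    sequences: dict[str, str],
    sheet: SampleSheet,
    rng: np.random.Generator,
) -> TruthTable:
    """Plant true SNPs genome-wide and PSVs/MSVs on duplicated arms, with
    per-sample true dosages drawn under the population design."""
    used: set[tuple[str, int]] = set()
    variants: list[TruthVariant] = []
    pops = sheet.populations  # includes the DH group
    pop_names = list(pops)
    n_samples = len(sheet)
    dh_set = set(sheet.dh_indices)

    def draw_position(chrom: str, lo: int, hi: int) -> tuple[str, int] | None:
        for _ in range(20):
            pos = int(rng.integers(lo, hi)) + 1
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos
        return None

    def alt_base(chrom: str, pos: int) -> tuple[str, str]:
        ref = sequences[chrom][pos - 1]
        choices = [b for b in "ACGT" if b != ref]
        return ref, choices[int(rng.integers(0, 3))]

    def outbred_and_dh_dosages(pop_freqs: dict[str, float], dh_residual: bool) -> np.ndarray:
        dos = np.zeros(n_samples, dtype=np.int8)
        for pop in pop_names:
            p = pop_freqs[pop]
            for i in pops[pop]:
                if i in dh_set:
                    dos[i] = 2 * int(rng.random() < p)
                    if dh_residual and rng.random() < cfg.residual_dh_het:
                        dos[i] = 1
                else:
                    dos[i] = int(rng.binomial(2, p))
        return dos

    # true SNPs, genome-wide
    for chrom, length in build.chrom_lengths.items():
        n_snp = rng.poisson(cfg.snp_density * length)
        for _ in range(n_snp):
            key = draw_position(chrom, 0, length)
            if key is None:
                continue
            ref, alt = alt_base(*key)
            p0 = float(rng.beta(*cfg.maf_beta))
            freqs = dict(zip(pop_names, _balding_nichols(p0, cfg.fst, len(pop_names), rng)))
            dos = outbred_and_dh_dosages(freqs, dh_residual=True)
            variants.append(TruthVariant(key[0], key[1], ref, alt, "true_snp", p0, dos))

    # PSVs and MSVs, on duplicated arms only
    dup_arms = [a for a in build.arms if a.name in build.duplicated_arm_names]
    for arm in dup_arms:
        n_psv = rng.poisson(cfg.psv_density * arm.length)
        for _ in range(n_psv):
            key = draw_position(arm.chrom, arm.start, arm.end)
            if key is None:
                continue
            ref, alt = alt_base(*key)
            variants.append(
                TruthVariant(
                    key[0], key[1], ref, alt, "psv", 0.5,
                    np.ones(n_samples, dtype=np.int8),
                )
            )
        n_msv = rng.poisson(cfg.msv_density * arm.length)
        for _ in range(n_msv):
            key = draw_position(arm.chrom, arm.start, arm.end)
            if key is None:
                continue
            ref, alt = alt_base(*key)
            p0 = float(rng.beta(*cfg.msv_beta))
            freqs = dict(zip(pop_names, _balding_nichols(p0, cfg.fst, len(pop_names), rng)))
            dos = outbred_and_dh_dosages(freqs, dh_residual=False)
            variants.append(TruthVariant(key[0], key[1], ref, alt, "msv", p0, dos))

    if cfg.high_depth_site_rate > 0:
        for v in variants:
            if rng.random() < cfg.high_depth_site_rate:
                v.high_depth = True

    variants.sort(key=lambda v: (v.chrom, v.pos))
    return TruthTable(variants, sheet)


def simulate_samples(
    cfg: SimConfig, truth: TruthTable, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site, per-sample (ref_reads, alt_reads) matrices.

    The expected alternate-read fraction per sample is the true dosage over
    the number of collapsed haplotype copies: dosage/2 for true SNPs, ~1/2 at
    PSVs in every sample, dosage/4 at MSVs (two copies of each of two
    paralogs), floored at the base-error rate. PSV fractions are not exactly
    1/2: collapsed paralogs show dispersed allelic ratios (mapping bias,
    copy-number differences), modelled as a per-site mean drawn from
    ``psv_site_bias_beta`` with per-sample Beta noise at concentration
    ``psv_read_concentration``; this is what grades the doubled-haploid
    heterozygote count across PSV loci.
    """
    n_sites = len(truth.variants)
    n_samples = len(truth.sheet)
    mu = rng.uniform(
        cfg.min_coverage, 2 * cfg.mean_coverage - cfg.min_coverage, size=n_samples
    )
    depth = rng.poisson(np.broadcast_to(mu, (n_sites, n_samples)))
    frac = np.empty((n_sites, n_samples))
    e = cfg.base_error_rate
    conc = cfg.psv_read_concentration
    for i, v in enumerate(truth.variants):
        d = v.dosages.astype(float)
        if v.cls == "psv":
            m = rng.beta(*cfg.psv_site_bias_beta)
            f = rng.beta(m * conc, (1.0 - m) * conc, size=n_samples)
        elif v.cls == "msv":
            f = d / 4.0
        else:
            f = d / 2.0
        frac[i] = np.clip(f, e, 1.0 - e)
        if v.high_depth:
            depth[i] *= 10
    alt = rng.binomial(depth, frac)
    ref = depth - alt
    return ref, alt


# ---------------------------------------------------------------------------
# Caller emission


def caller_drop_rate(target_concordance: float, unique_false_rate: float) -> float:
    """Per-caller site-miss probability giving the target combined same-ALT
    share.

    With inclusion probability x = 1 - d per caller and f false unique sites
    per caller (as a fraction of planted sites), the expected combined-set
    share solves x^2 = c * (x^2 + 2x(1-x) + 2f), a quadratic in x.
    """
    c, f = target_concordance, unique_false_rate
    x = (c + np.sqrt(c * c + 2 * c * f * (1 + c))) / (1 + c)
    return float(1 - min(x, 1.0))


def _draw_qual(cfg: SimConfig, rng: np.random.Generator) -> float:
    if rng.random() < cfg.qual_low_rate:
        return float(np.round(rng.uniform(1.0, 30.0), 2))
    return float(np.round(30.01 + rng.exponential(150.0), 2))


def emit_callsets(
    cfg: SimConfig,
    truth: TruthTable,
    ref_reads: np.ndarray,
    alt_reads: np.ndarray,
    sequences: dict[str, str],
    indel_positions: dict[str, list[int]],
    rng: np.random.Generator,
) -> tuple[list[VariantSite], list[VariantSite]]:
    """Two caller outputs over the same read data.

    Each caller independently misses sites at the rate derived from the
    configured target concordance, adds unique false sites, reports a
    different ALT at shared sites at a small rate, and draws its own QUAL.
    Indels are emitted identically by both callers so the proximity filter
    can see them.
    """
    sheet = truth.sheet
    n_samples = len(sheet)
    drop = caller_drop_rate(cfg.target_concordance, cfg.caller_unique_false_rate)

    def site(
        v_chrom: str, v_pos: int, ref: str, alt: str, qual: float,
        r_row: np.ndarray, a_row: np.ndarray,
    ) -> VariantSite:
        calls = [
            SampleCall(ref_reads=int(r_row[j]), alt_reads=int(a_row[j]),
                       genotype=Genotype.MISSING)
            for j in range(n_samples)
        ]
        return VariantSite(v_chrom, v_pos, ref, alt_alleles=[alt], qual=qual,
                           per_sample=calls)

    out_a: list[VariantSite] = []
    out_b: list[VariantSite] = []
    used = set(truth.by_key)
    for i, v in enumerate(truth.variants):
        in_a = rng.random() >= drop
        in_b = rng.random() >= drop
        alt_a = alt_b = v.alt
        if in_a and in_b and rng.random() < cfg.alt_disagreement_rate:
            others = [b for b in "ACGT" if b not in (v.ref, v.alt)]
            alt_b = others[int(rng.integers(0, len(others)))]
        if in_a:
            out_a.append(site(v.chrom, v.pos, v.ref, alt_a, _draw_qual(cfg, rng),
                              ref_reads[i], alt_reads[i]))
        if in_b:
            out_b.append(site(v.chrom, v.pos, v.ref, alt_b, _draw_qual(cfg, rng),
                              ref_reads[i], alt_reads[i]))

    # caller-unique false sites: low-level noise at otherwise invariant positions
    chrom_names = list(sequences)
    n_false = rng.binomial(len(truth.variants), cfg.caller_unique_false_rate)
    for out in (out_a, out_b):
        for _ in range(n_false):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            length = len(sequences[chrom])
            pos = int(rng.integers(0, length)) + 1
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            ref = sequences[chrom][pos - 1]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
            depth = rng.poisson(cfg.mean_coverage, size=n_samples)
            a_row = rng.binomial(depth, 0.02)
            out.append(site(chrom, pos, ref, alt, _draw_qual(cfg, rng),
                            depth - a_row, a_row))

    # indels, identical in both callers
    for chrom, positions in indel_positions.items():
        seq = sequences[chrom]
        for pos in positions:
            ref = seq[pos - 1 : pos + 1]
            alt = ref[0]
            depth = rng.poisson(cfg.mean_coverage, size=n_samples)
            r_row, a_row = depth, np.zeros(n_samples, dtype=int)
            qual = float(np.round(31.0 + rng.exponential(100.0), 2))
            out_a.append(site(chrom, pos, ref, alt, qual, r_row, a_row))
            out_b.append(site(chrom, pos, ref, alt, qual, r_row, a_row))

    out_a.sort(key=lambda s: (s.chrom, s.pos))
    out_b.sort(key=lambda s: (s.chrom, s.pos))
    return out_a, out_b


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator under the configured seed."""
    rng = np.random.default_rng(cfg.seed)
    sheet = build_sample_sheet(cfg)
    seqs, build, tracts, indels = simulate_genome(cfg, rng)
    truth = plant_variants(cfg, build, seqs, sheet, rng)
    ref_reads, alt_reads = simulate_samples(cfg, truth, rng)
    callset_a, callset_b = emit_callsets(
        cfg, truth, ref_reads, alt_reads, seqs, indels, rng
    )
    return SimResult(cfg, seqs, build, sheet, truth, callset_a, callset_b, tracts, indels)


# ---------------------------------------------------------------------------
# Toy gene models for annotation runs


def write_toy_gff3(build: GenomeBuild, sequences: dict[str, str], path) -> None:
    """A few two-exon coding genes per chromosome (coordinates only; the
    underlying sequence is whatever the simulated genome contains)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        g = 0
        for chrom, length in build.chrom_lengths.items():
            # alternating spacing: short gaps give overlapping flank regions
            # (several effects per SNP), long gaps leave intergenic stretches
            starts = []
            pos = 2_000
            while pos < length - 10_000:
                starts.append(pos)
                pos += 12_000 if len(starts) % 2 else 20_000
            for start in starts:
                g += 1
                strand = "+" if g % 2 else "-"
                gid, tid = f"gene{g}", f"tx{g}"
                e1 = (start, start + 1_200)
                e2 = (start + 2_000, start + 3_400)
                cds1 = (start + 300, start + 1_200)
                cds2 = (start + 2_000, start + 3_002)  # 900 + 1002 bp: divisible by 3
                utr5, utr3 = (start, start + 300), (start + 3_002, start + 3_400)
                if strand == "-":
                    utr5, utr3 = utr3, utr5
                gene_end = start + 3_400

                def line(ftype, s, e, attrs):
                    fh.write(
                        f"{chrom}\ttoy\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"
                    )

                line("gene", start, gene_end, f"ID={gid}")
                line("mRNA", start, gene_end, f"ID={tid};Parent={gid}")
                for s, e in (e1, e2):
                    line("exon", s, e, f"Parent={tid}")
                for s, e in (cds1, cds2):
                    line("CDS", s, e, f"Parent={tid}")
                line("five_prime_UTR", *utr5, f"Parent={tid}")
                line("three_prime_UTR", *utr3, f"Parent={tid}")
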