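"""Lightweight SnpEff-style effect annotation of SNPs against gene models.

Each bi-allelic SNP receives one Sequence Ontology effect term per
overlapping transcript (plus upstream/downstream records for nearby genes,
and intergenic_region as the fallback), drawn from a fixed 20-term
vocabulary with HIGH/MODERATE/LOW/MODIFIER impact tiers. Coding effects are
resolved by strand-aware codon comparison against the reference sequence.

Conventions (configurable): upstream/downstream distance 5 kb; splice donor
and acceptor are the first and last two intronic bases; the splice region
covers intronic bases 3-8 from a junction. Within the CDS the codon-change
term takes precedence over the splice-region label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .model import VariantSite

# SO term -> impact, in printed summary order
SO_IMPACT: dict[str, str] = {
    "stop_gained": "HIGH",
    "splice_donor_variant": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "missense_variant": "MODERATE",
    "splice_region_variant": "LOW",
    "synonymous_variant": "LOW",
    "5_prime_UTR_premature_start_codon_gain_variant": "LOW",
    "stop_retained_variant": "LOW",
    "initiator_codon_variant": "LOW",
    "non_coding_transcript_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "intergenic_region": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "3_prime_UTR_variant": "MODIFIER",
    "intragenic_variant": "MODIFIER",
    "5_prime_UTR_variant": "MODIFIER",
    "non_coding_transcript_exon_variant": "MODIFIER",
}

_ALT_START_CODONS = {"CTG", "GTG", "TTG"}  # recognised alternative initiators


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def finalise(self) -> None:
        for lst in (self.exons, self.cds, self.utr5, self.utr3):
            lst.sort()

    @property
    def start(self) -> int:
        return self.exons[0][0] if self.exons else 0

    @property
    def end(self) -> int:
        return self.exons[-1][1] if self.exons else 0

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass(frozen=True)
class EffectRecord:
    chrom: str
    pos: int
    so_term: str
    impact: str
    gene_id: str | None = None
    transcript_id: str | None = None

    def ann_string(self) -> str:
        return f"{self.so_term}|{self.impact}|{self.gene_id or ''}"


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GFF3 parsing


def _gff_attrs(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> dict[str, list[GeneModel]]:
    """Gene models from GFF3 (gene, mRNA/transcript, exon, CDS, UTRs),
    indexed by chromosome."""
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            s, e = int(start) - 1, int(end)  # GFF 1-based inclusive -> half-open
            a = _gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID", f"gene:{chrom}:{s}")
                genes[gid] = GeneModel(gid, chrom, strand, s, e)
            elif ftype in ("mRNA", "transcript", "ncRNA", "lnc_RNA"):
                tid = a.get("ID", f"tx:{chrom}:{s}")
                gid = a.get("Parent", tid)
                tx = Transcript(tid, gid, chrom, strand)
                transcripts[tid] = tx
                if gid not in genes:
                    genes[gid] = GeneModel(gid, chrom, strand, s, e)
                genes[gid].transcripts.append(tx)
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = a.get("Parent")
                if parent is None or parent not in transcripts:
                    continue
                tx = transcripts[parent]
                dest = {
                    "exon": tx.exons,
                    "CDS": tx.cds,
                    "five_prime_UTR": tx.utr5,
                    "three_prime_UTR": tx.utr3,
                }[ftype]
                dest.append((s, e))
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes.values():
        for tx in g.transcripts:
            tx.finalise()
            if not tx.exons and tx.cds:
                tx.exons = list(tx.cds)
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)
    return by_chrom


# ---------------------------------------------------------------------------
# Codon-change classification


def classify_codon_change(ref_codon: str, alt_codon: str, is_start: bool = False) -> str:
    """SO term for a single-codon substitution (codons in coding orientation)."""
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    if is_start:
        if alt_codon == ref_codon:
            return "synonymous_variant"
        if alt_codon == "ATG" or alt_codon in _ALT_START_CODONS:
            return "initiator_codon_variant"
        return "start_lost"
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == "*":
        return "stop_retained_variant" if aa_alt == "*" else "stop_lost"
    if aa_alt == "*":
        return "stop_gained"
    return "synonymous_variant" if aa_ref == aa_alt else "missense_variant"


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _coding_effect(tx: Transcript, pos0: int, ref: str, alt: str, seq: str) -> str:
    """Effect of a SNP inside the CDS of a coding transcript."""
    blocks = tx.cds if tx.strand == "+" else list(reversed(tx.cds))
    offset = 0
    cds_pos = None
    for s, e in blocks:
        if s <= pos0 < e:
            cds_pos = offset + (pos0 - s if tx.strand == "+" else e - 1 - pos0)
            break
        offset += e - s
    if cds_pos is None:
        raise AnnotationError(f"position {pos0 + 1} not in CDS of {tx.transcript_id}")
    codon_idx, in_codon = divmod(cds_pos, 3)

    # genomic coordinates of the three coding positions of this codon
    coding_coords: list[int] = []
    need = range(codon_idx * 3, codon_idx * 3 + 3)
    offset = 0
    for s, e in blocks:
        for k in need:
            if offset <= k < offset + (e - s):
                coding_coords.append(
                    s + (k - offset) if tx.strand == "+" else e - 1 - (k - offset)
                )
        offset += e - s
    if len(coding_coords) < 3:  # codon truncated by an incomplete CDS
        return "synonymous_variant"

    bases = [seq[c] for c in coding_coords]
    if tx.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
    ref_codon = "".join(bases)
    expected = ref if tx.strand == "+" else ref.translate(_COMPLEMENT)
    if ref_codon[in_codon] != expected:
        raise AnnotationError(
            f"reference mismatch at {tx.chrom}:{pos0 + 1}: "
            f"VCF REF {ref!r} vs genome {seq[pos0]!r}"
        )
    alt_base = alt if tx.strand == "+" else alt.translate(_COMPLEMENT)
    alt_codon = ref_codon[:in_codon] + alt_base + ref_codon[in_codon + 1 :]
    return classify_codon_change(ref_codon, alt_codon, is_start=(codon_idx == 0))


def _intron_effect(tx: Transcript, pos0: int, splice_region_intron: tuple[int, int]) -> str:
    lo, hi = splice_region_intron
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        if e1 <= pos0 < s2:
            d_left = pos0 - e1 + 1  # 1-based distance into intron from left exon
            d_right = s2 - pos0  # from right exon
            donor_left = tx.strand == "+"
            if d_left <= 2:
                return "splice_donor_variant" if donor_left else "splice_acceptor_variant"
            if d_right <= 2:
                return "splice_acceptor_variant" if donor_left else "splice_donor_variant"
            if lo <= d_left <= hi or lo <= d_right <= hi:
                return "splice_region_variant"
            return "intron_variant"
    return "intron_variant"


def _utr5_effect(tx: Transcript, pos0: int, ref: str, alt: str, seq: str) -> str:
    """5' UTR SNP; detects creation of a premature upstream start codon."""
    lo = max(pos0 - 2, 0)
    hi = min(pos0 + 3, len(seq))
    ref_win = seq[lo:hi]
    alt_win = ref_win[: pos0 - lo] + alt + ref_win[pos0 - lo + 1 :]
    if tx.strand == "-":
        ref_win, alt_win = _revcomp(ref_win), _revcomp(alt_win)
    if "ATG" in alt_win and "ATG" not in ref_win:
        return "5_prime_UTR_premature_start_codon_gain_variant"
    return "5_prime_UTR_variant"


def _in(blocks: Iterable[tuple[int, int]], pos0: int) -> bool:
    return any(s <= pos0 < e for s, e in blocks)


def _transcript_effect(
    tx: Transcript,
    pos0: int,
    ref: str,
    alt: str,
    seq: str,
    splice_region_intron: tuple[int, int],
) -> str:
    in_exon = _in(tx.exons, pos0)
    if not tx.is_coding:
        return (
            "non_coding_transcript_exon_variant"
            if in_exon
            else "non_coding_transcript_variant"
        )
    if not in_exon:
        return _intron_effect(tx, pos0, splice_region_intron)
    if _in(tx.cds, pos0):
        return _coding_effect(tx, pos0, ref, alt, seq)
    if _in(tx.utr5, pos0):
        return _utr5_effect(tx, pos0, ref, alt, seq)
    if _in(tx.utr3, pos0):
        return "3_prime_UTR_variant"
    # exonic, outside CDS and undeclared UTRs: side relative to the CDS
    cds_lo = tx.cds[0][0]
    before = pos0 < cds_lo
    if (tx.strand == "+") == before:
        return _utr5_effect(tx, pos0, ref, alt, seq)
    return "3_prime_UTR_variant"


def annotate_site(
    site: VariantSite,
    models_by_chrom: dict[str, list[GeneModel]],
    reference: dict[str, str],
    updownstream: int = 5_000,
    splice_region_intron: tuple[int, int] = (3, 8),
) -> list[EffectRecord]:
    """Effect records for one bi-allelic SNP: one per overlapping transcript,
    one per gene within the upstream/downstream distance, intergenic_region
    if nothing else applies.

    Raises AnnotationError when the VCF REF disagrees with the reference
    base.
    """
    if not site.is_biallelic_snp:
        raise AnnotationError(f"{site.chrom}:{site.pos} is not a bi-allelic SNP")
    seq = reference.get(site.chrom)
    pos0 = site.pos - 1
    if seq is not None and seq[pos0] != site.ref_allele:
        raise AnnotationError(
            f"reference mismatch at {site.chrom}:{site.pos}: "
            f"VCF REF {site.ref_allele!r} vs genome {seq[pos0]!r}"
        )
    records: list[EffectRecord] = []

    def add(term: str, gene: str | None = None, tx: str | None = None) -> None:
        records.append(
            EffectRecord(site.chrom, site.pos, term, SO_IMPACT[term], gene, tx)
        )

    for gene in models_by_chrom.get(site.chrom, []):
        if gene.start <= pos0 < gene.end:
            in_tx = False
            for tx in gene.transcripts:
                if tx.start <= pos0 < tx.end:
                    in_tx = True
                    term = _transcript_effect(
                        tx, pos0, site.ref_allele, site.alt_alleles[0],
                        seq if seq is not None else "",
                        splice_region_intron,
                    )
                    add(term, gene.gene_id, tx.transcript_id)
            if not in_tx:
                add("intragenic_variant", gene.gene_id)
        elif gene.start - updownstream <= pos0 < gene.start:
            add(
                "upstream_gene_variant" if gene.strand == "+" else "downstream_gene_variant",
                gene.gene_id,
            )
        elif gene.end <= pos0 < gene.end + updownstream:
            add(
                "downstream_gene_variant" if gene.strand == "+" else "upstream_gene_variant",
                gene.gene_id,
            )
    if not records:
        add("intergenic_region")
    return records


def effect_summary(records: Iterable[EffectRecord]) -> list[tuple[str, str, int]]:
    """Counts per (SO term, impact), zero-filled, in the fixed vocabulary
    order. Counts are effects, not SNPs: one SNP may contribute several."""
    counts = {term: 0 for term in SO_IMPACT}
    for r in records:
        counts[r.so_term] += 1
    return [(term, SO_IMPACT[term], counts[term]) for term in SO_IMPACT]
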