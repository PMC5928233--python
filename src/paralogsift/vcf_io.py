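"""Readers and writers for the formats the pipeline touches.

VCF access goes through :mod:`pysam`; FASTA reading through :mod:`pyfaidx`.
The VCF surface is deliberately narrow — CHROM, POS, REF, ALT, QUAL and the
per-sample GT:AD:DP fields — because those are the only fields the filters
consume. Records are carried losslessly at parse time (multi-allelic sites and
indels included); restriction to bi-allelic SNPs is a filtering decision, not
an I/O one.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Sequence

import pysam
from pyfaidx import Fasta

from .model import Genotype, MaskRegion, SampleCall, SampleEntry, SampleSheet, VariantSite


class VcfParseError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


_GT_TO_VCF = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}


def _genotype_from_gt(gt) -> Genotype:
    if gt is None or any(a is None for a in gt):
        return Genotype.MISSING
    alleles = set(gt)
    if alleles == {0}:
        return Genotype.HOM_REF
    if alleles == {0, 1}:
        return Genotype.HET
    if 0 not in alleles:
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf(path: str | os.PathLike, sheet: SampleSheet) -> Iterator[VariantSite]:
    """Stream sites from a VCF in file order, samples re-ordered to the sheet.

    Raises ConfigurationError if a sheet sample is absent from the VCF, and
    VcfParseError (naming the record number) on a malformed record.
    """
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        missing = [s for s in sheet.sample_ids if s not in vcf_samples]
        if missing:
            raise ConfigurationError(
                f"samples in sheet but not in VCF {path}: {missing}"
            )
        recno = 0
        it = iter(vf)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except Exception as exc:  # malformed record from htslib
                raise VcfParseError(
                    f"{path}: malformed VCF record #{recno + 1}: {exc}"
                ) from exc
            recno += 1
            try:
                yield _site_from_record(rec, sheet)
            except VcfParseError:
                raise
            except Exception as exc:
                raise VcfParseError(
                    f"{path}: malformed VCF record #{recno} at "
                    f"{rec.chrom}:{rec.pos}: {exc}"
                ) from exc


def _site_from_record(rec: "pysam.VariantRecord", sheet: SampleSheet) -> VariantSite:
    alts = list(rec.alts) if rec.alts else []
    calls: list[SampleCall] = []
    for sid in sheet.sample_ids:
        s = rec.samples[sid]
        ad = s.get("AD")
        ref_reads = alt_reads = None
        if ad is not None and len(ad) >= 2 and ad[0] is not None:
            ref_reads = int(ad[0])
            # reads supporting any alternate allele
            alt_reads = int(sum(a for a in ad[1:] if a is not None))
        dp = s.get("DP")
        gt = s.get("GT") if "GT" in s else None
        calls.append(
            SampleCall(
                ref_reads=ref_reads,
                alt_reads=alt_reads,
                genotype=_genotype_from_gt(gt),
                depth=int(dp) if dp is not None else None,
            )
        )
    info = {}
    for k, v in rec.info.items():
        if isinstance(v, tuple):
            v = v[0] if len(v) == 1 else ",".join(str(x) for x in v)
        info[k] = v
    return VariantSite(
        chrom=rec.chrom,
        pos=rec.pos,
        ref_allele=rec.ref,
        alt_alleles=alts,
        qual=float(rec.qual) if rec.qual is not None else 0.0,
        per_sample=calls,
        info_flags=info,
    )


def write_vcf(
    sites: Iterable[VariantSite],
    sheet: SampleSheet,
    path: str | os.PathLike,
    contig_lengths: dict[str, int] | None = None,
    sort: bool = False,
) -> None:
    """Write sites as an uncompressed VCF 4.2 file.

    Input must be sorted by (chrom, pos) unless ``sort=True``; chromosome
    order is first-appearance order (or ``contig_lengths`` order if given).
    """
    sites = list(sites)
    if sort:
        order: dict[str, int] = {}
        for s in sites:
            order.setdefault(s.chrom, len(order))
        sites.sort(key=lambda s: (order[s.chrom], s.pos))

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    contigs: list[str] = []
    if contig_lengths:
        contigs = list(contig_lengths)
    for s in sites:
        if s.chrom not in contigs:
            contigs.append(s.chrom)
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            header.contigs.add(c, length=contig_lengths[c])
        else:
            header.contigs.add(c)
    info_keys: dict[str, type] = {}
    for s in sites:
        for k, v in s.info_flags.items():
            info_keys.setdefault(k, type(v))
    for k, t in info_keys.items():
        vtype = {int: "Integer", float: "Float", bool: "Flag"}.get(t, "String")
        number = "0" if vtype == "Flag" else "1"
        header.add_line(
            f'##INFO=<ID={k},Number={number},Type={vtype},Description="{k}">'
        )
    for sid in sheet.sample_ids:
        header.add_sample(sid)

    contig_rank = {c: i for i, c in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        prev: tuple[int, int] | None = None
        for s in sites:
            key = (contig_rank[s.chrom], s.pos)
            if prev is not None and key < prev:
                raise ValueError(
                    f"unsorted input at {s.chrom}:{s.pos} (pass sort=True)"
                )
            prev = key
            rec = out.new_record(
                contig=s.chrom,
                start=s.pos - 1,
                alleles=[s.ref_allele, *s.alt_alleles],
                qual=s.qual,
            )
            for k, v in s.info_flags.items():
                rec.info[k] = True if isinstance(v, bool) else v
            for i, sid in enumerate(sheet.sample_ids):
                call = s.per_sample[i]
                rs = rec.samples[sid]
                rs["GT"] = _GT_TO_VCF[call.genotype]
                if call.ref_reads is not None and call.alt_reads is not None:
                    ad = [call.ref_reads, call.alt_reads]
                    ad += [0] * (len(s.alt_alleles) - 1)
                    rs["AD"] = tuple(ad)
                if call.depth is not None or (
                    call.ref_reads is not None and call.alt_reads is not None
                ):
                    rs["DP"] = call.total_depth()
            out.write(rec)


# ---------------------------------------------------------------------------
# BED


def merge_regions(regions: Iterable[MaskRegion]) -> list[MaskRegion]:
    """Union of intervals, per chromosome, as a sorted non-overlapping list.

    Touching intervals ([0,5) and [5,9)) are merged."""
    by_chrom: dict[str, list[MaskRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: list[MaskRegion] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for r in ivs[1:]:
            if r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                out.append(MaskRegion(chrom, cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        out.append(MaskRegion(chrom, cur_s, cur_e))
    return out


def read_bed(path: str | os.PathLike) -> list[MaskRegion]:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise VcfParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise VcfParseError(
                    f"{path}:{lineno}: BED interval start >= end ({start} >= {end})"
                )
            regions.append(MaskRegion(chrom, start, end))
    return regions


def write_bed(regions: Iterable[MaskRegion], path: str | os.PathLike) -> None:
    merged = merge_regions(regions)
    with open(path, "w") as fh:
        for r in merged:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Chromosome name -> uppercase sequence, preserving file order."""
    fa = Fasta(str(path), rebuild=True, build_index=True)
    out = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    return out


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Sample sheet (3-column TSV: sample_id, population, DH flag 0/1)


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise VcfParseError(
                    f"{path}:{lineno}: expected 3 columns (sample_id, population, dh)"
                )
            entries.append(
                SampleEntry(fields[0], fields[1], fields[2].strip() in ("1", "true", "True"))
            )
    return SampleSheet(entries)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\tpopulation\tdh\n")
        for e in sheet:
            fh.write(f"{e.sample_id}\t{e.population}\t{1 if e.is_dh else 0}\n")
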