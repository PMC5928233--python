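"""End-to-end orchestration: concordance -> intersection -> filter cascade ->
doubled-haploid screen -> statistics -> (optional) effect annotation.

The trusted core of the database is the set of sites called by both callers
at the same position with the same alternate allele; the cascade and the DH
screen run on that intersection, and every summary table is computed from
the retained set. The manifest records every count and the partition
invariant retained + flagged == cascade survivors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import popgen
from .annotation import GeneModel, annotate_site, effect_summary
from .concordance import classify_sites, concordance_summary, intersect_same_alt
from .duplication import arm_density, dh_screen, threshold_sweep
from .model import GenomeBuild, MaskRegion, SampleSheet, VariantSite
from .site_filters import FilterConfig, apply_filter_cascade, dust_mask_genome
from .vcf_io import write_vcf


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    counts: dict = field(default_factory=dict)
    concordance: dict = field(default_factory=dict)
    ledger: list = field(default_factory=list)
    sweep: list = field(default_factory=list)
    arm_density: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "concordance": self.concordance,
                "ledger": self.ledger,
                "sweep": self.sweep,
                "arm_density": self.arm_density,
                "thresholds": self.thresholds,
                "outputs": {k: str(v) for k, v in self.outputs.items()},
            },
            indent=2,
            sort_keys=True,
        )

    @property
    def content_hash(self) -> str:
        payload = self.to_json().encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunResult:
    manifest: RunManifest
    retained: list[VariantSite]
    flagged: list[VariantSite]
    screen_results: list
    density_rows: list
    genome_density: object
    population_rows: list
    pi_windows: list
    mean_pi: float
    maf_counts: object
    maf_prop_rare: float
    effects: list | None = None


def run_all(
    callset_a: Sequence[VariantSite],
    callset_b: Sequence[VariantSite],
    sheet: SampleSheet,
    build: GenomeBuild,
    masks: Sequence[MaskRegion] | None = None,
    sequences: dict[str, str] | None = None,
    cfg: FilterConfig | None = None,
    dh_threshold: int = 2,
    models_by_chrom: dict[str, list[GeneModel]] | None = None,
    pi_window: int = 20_000,
    outdir: str | Path | None = None,
) -> RunResult:
    """Run the full analysis on two call sets.

    Masks may be given directly or computed from ``sequences`` with the
    DUST-style masker. Any stage failure raises PipelineError naming the
    stage.
    """
    cfg = cfg or FilterConfig()
    manifest = RunManifest()
    manifest.thresholds = {
        "min_qual": cfg.min_qual,
        "indel_distance": cfg.indel_distance,
        "max_depth": cfg.max_depth,
        "min_samples": cfg.resolved_min_samples(len(sheet)),
        "min_alt_reads": cfg.min_alt_reads,
        "min_ref_reads": cfg.min_ref_reads,
        "dust_window": cfg.dust_window,
        "dust_threshold": cfg.dust_threshold,
        "dh_threshold": dh_threshold,
        "pi_window": pi_window,
    }

    try:
        snps_a = [s for s in callset_a if s.is_biallelic_snp]
        snps_b = [s for s in callset_b if s.is_biallelic_snp]
        records = classify_sites(snps_a, snps_b)
        summary = concordance_summary(records)
        manifest.concordance = {
            "n_a_only": summary.n_a_only,
            "n_b_only": summary.n_b_only,
            "n_same_alt": summary.n_same_alt,
            "n_diff_alt": summary.n_diff_alt,
            "pct_same_alt_of_combined": summary.pct_same_alt_of_combined,
            "pct_diff_alt_of_shared": summary.pct_diff_alt_of_shared,
        }
        core = intersect_same_alt(list(callset_a), records)
    except Exception as exc:
        raise PipelineError("concordance", exc) from exc

    try:
        if masks is None:
            masks = dust_mask_genome(sequences, cfg) if sequences else []
        # indel proximity must see the raw call sets, so feed the union of
        # indels from both callers alongside the intersected SNP core
        indel_carriers = [s for s in list(callset_a) + list(callset_b) if s.is_indel]
        survivors, ledger = apply_filter_cascade(
            list(core) + indel_carriers, masks, cfg, sheet
        )
        manifest.ledger = ledger.to_rows()
    except Exception as exc:
        raise PipelineError("filter_cascade", exc) from exc

    try:
        retained, flagged, screen = dh_screen(survivors, sheet, threshold=dh_threshold)
        if len(retained) + len(flagged) != len(survivors):
            raise AssertionError("retained + flagged != cascade survivors")
        sweep = threshold_sweep(survivors, sheet)
        manifest.sweep = [
            (r.label, r.min_het, r.n_flagged, round(r.mean_outbred_ho, 4),
             round(r.pct_hwe_deviation, 2))
            for r in sweep
        ]
        arms = arm_density(flagged, build)
        manifest.arm_density = [
            (a.arm, a.length, a.n_flagged, a.is_delayed_rediploidization)
            for a in arms
        ]
    except Exception as exc:
        raise PipelineError("dh_screen", exc) from exc

    try:
        density_rows, genome_density = popgen.snp_density_table(retained, build)
        pop_rows = popgen.population_polymorphism(retained, sheet)
        pi_windows, mean_pi = popgen.nucleotide_diversity_windows(
            retained, build, window=pi_window
        )
        maf_counts, _, prop_rare = popgen.maf_spectrum(retained)
        manifest.counts = {
            "input_a": len(callset_a),
            "input_b": len(callset_b),
            "snps_a": len(snps_a),
            "snps_b": len(snps_b),
            "intersection_same_alt": len(core),
            "cascade_survivors": len(survivors),
            "retained_snps": len(retained),
            "flagged_psv_msv": len(flagged),
            "genome_snp_rate_bp": genome_density.rate_bp,
            "mean_pi": mean_pi,
            "maf_prop_below_0.05": prop_rare,
        }
    except Exception as exc:
        raise PipelineError("stats", exc) from exc

    effects = None
    if models_by_chrom is not None:
        try:
            effects = []
            for s in retained:
                effects.extend(
                    annotate_site(s, models_by_chrom, sequences or {})
                )
            manifest.counts["n_effects"] = len(effects)
        except Exception as exc:
            raise PipelineError("annotation", exc) from exc

    result = RunResult(
        manifest=manifest,
        retained=retained,
        flagged=flagged,
        screen_results=screen,
        density_rows=density_rows,
        genome_density=genome_density,
        population_rows=pop_rows,
        pi_windows=pi_windows,
        mean_pi=mean_pi,
        maf_counts=maf_counts,
        maf_prop_rare=prop_rare,
        effects=effects,
    )
    if outdir is not None:
        _write_outputs(result, sheet, build, Path(outdir))
    return result


def _write_outputs(
    result: RunResult, sheet: SampleSheet, build: GenomeBuild, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    m = result.manifest
    lengths = build.chrom_lengths
    paths = {
        "retained_vcf": outdir / "retained_snps.vcf",
        "flagged_vcf": outdir / "putative_psv_msv.vcf",
        "ledger": outdir / "filter_ledger.tsv",
        "concordance": outdir / "concordance_summary.tsv",
        "sweep": outdir / "dh_threshold_sweep.tsv",
        "arm_density": outdir / "arm_density.tsv",
        "density": outdir / "snp_density.tsv",
        "populations": outdir / "population_polymorphism.tsv",
        "pi": outdir / "pi_windows.bedgraph",
        "manifest": outdir / "manifest.json",
    }
    write_vcf(result.retained, sheet, paths["retained_vcf"], contig_lengths=lengths)
    write_vcf(result.flagged, sheet, paths["flagged_vcf"], contig_lengths=lengths)
    with open(paths["ledger"], "w") as fh:
        fh.write("stage\tentering\tpassing\tremoved\n")
        for stage, entering, passing, removed in m.ledger:
            fh.write(f"{stage}\t{entering}\t{passing}\t{removed}\n")
    with open(paths["concordance"], "w") as fh:
        fh.write("\t".join(m.concordance) + "\n")
        fh.write("\t".join(str(v) for v in m.concordance.values()) + "\n")
    with open(paths["sweep"], "w") as fh:
        fh.write("label\tmin_het\tn_flagged\tmean_outbred_ho\tpct_hwe_deviation\n")
        for row in m.sweep:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["arm_density"], "w") as fh:
        fh.write("arm\tlength\tn_flagged\tdelayed_rediploidization\n")
        for arm, length, n, dup in m.arm_density:
            fh.write(f"{arm}\t{length}\t{n}\t{int(dup)}\n")
    with open(paths["density"], "w") as fh:
        fh.write("chrom\tlength_bp\tn_snps\trate_bp\n")
        for r in result.density_rows + [result.genome_density]:
            fh.write(f"{r.chrom}\t{r.length}\t{r.n_snps}\t{r.rate_bp}\n")
    with open(paths["populations"], "w") as fh:
        fh.write(
            "population\tn_fish\tn_sites_full_data\tn_polymorphic\t"
            "pct_polymorphic\tmean_maf\tmean_ho\n"
        )
        for r in result.population_rows:
            fh.write(
                f"{r.population}\t{r.n_fish}\t{r.n_sites_full_data}\t"
                f"{r.n_polymorphic}\t{r.pct_polymorphic:g}\t"
                f"{r.mean_maf_polymorphic:.2f}\t{r.mean_ho_polymorphic:.2f}\n"
            )
    with open(paths["pi"], "w") as fh:
        for w in result.pi_windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.pi:.6g}\n")
    if result.effects is not None:
        paths["effects"] = outdir / "effect_summary.tsv"
        with open(paths["effects"], "w") as fh:
            fh.write("so_term\timpact\tn_effects\n")
            for term, impact, n in effect_summary(result.effects):
                fh.write(f"{term}\t{impact}\t{n}\n")
    m.outputs = {k: str(v) for k, v in paths.items()}
    paths["manifest"].write_text(m.to_json() + "\n")
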