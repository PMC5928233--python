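"""Shared fixtures: small hand-built panels and one session-scoped synthetic
study reused by the integration and acceptance tests."""

from __future__ import annotations

import dataclasses

import pytest

from paralogsift.model import (
    Genotype,
    SampleCall,
    SampleEntry,
    SampleSheet,
    VariantSite,
)
from paralogsift.pipeline import run_all
from paralogsift.simulate import SimConfig, simulate

GT = {
    "0": Genotype.HOM_REF,
    "1": Genotype.HET,
    "2": Genotype.HOM_ALT,
    ".": Genotype.MISSING,
}


def site_from_genotypes(
    chrom: str,
    pos: int,
    genotypes: str,
    ref: str = "A",
    alt: str = "G",
    qual: float = 100.0,
) -> VariantSite:
    """Site with genotypes given as a string of 0/1/2/. per sample."""
    calls = [SampleCall(genotype=GT[g]) for g in genotypes]
    return VariantSite(chrom, pos, ref, [alt], qual, calls)


def site_from_depths(
    chrom: str,
    pos: int,
    depths: list[tuple[int, int]],
    ref: str = "A",
    alt: str = "G",
    qual: float = 100.0,
) -> VariantSite:
    """Site with per-sample (ref_reads, alt_reads)."""
    calls = [SampleCall(ref_reads=r, alt_reads=a) for r, a in depths]
    return VariantSite(chrom, pos, ref, [alt], qual, calls)


def make_sheet(n_outbred: int, n_dh: int, pop: str = "pop1") -> SampleSheet:
    entries = [SampleEntry(f"S{i}", pop, False) for i in range(n_outbred)]
    entries += [SampleEntry(f"D{i}", "DHline", True) for i in range(n_dh)]
    return SampleSheet(entries)


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study: 61 samples, 480 kb genome, one
    duplicated arm pair, planted artifacts, ~80% caller concordance."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim):
    res = default_sim
    return run_all(
        res.callset_a, res.callset_b, res.sheet, res.build, sequences=res.sequences
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Artifact-free study with perfect caller agreement, for estimator
    recovery checks that should not be confounded by designed losses."""
    cfg = dataclasses.replace(
        SimConfig(seed=1).artifact_free(),
        target_concordance=1.0,
        caller_unique_false_rate=0.0,
        alt_disagreement_rate=0.0,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def clean_run(clean_sim):
    res = clean_sim
    return run_all(
        res.callset_a, res.callset_b, res.sheet, res.build, sequences=res.sequences
    )
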