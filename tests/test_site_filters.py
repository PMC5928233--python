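"""Filter-cascade predicates, the DUST-style masker, and cascade accounting."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paralogsift.model import Genotype, MaskRegion, SampleCall, VariantSite
from paralogsift.site_filters import (
    FilterConfig,
    MaskIndex,
    apply_filter_cascade,
    call_genotype,
    collect_indel_positions,
    dust_mask,
    filter_max_depth,
    filter_min_samples,
    filter_qual_biallelic,
    near_indel,
)
from conftest import make_sheet, site_from_depths

CFG = FilterConfig()


def snp(pos, qual=100.0, chrom="chr1", alts=("G",), ref="A", depths=((10, 10),)):
    calls = [SampleCall(ref_reads=r, alt_reads=a) for r, a in depths]
    return VariantSite(chrom, pos, ref, list(alts), qual, calls)


class TestQualStage:
    @pytest.mark.parametrize(
        "qual,expected",
        [(31.0, True), (30.0, False), (30.01, True), (29.0, False)],
    )
    def test_qual_strictly_above_threshold(self, qual, expected):
        ok, _ = filter_qual_biallelic(snp(100, qual=qual), {}, CFG)
        assert ok is expected

    def test_multiallelic_and_indel_alleles_rejected(self):
        assert not filter_qual_biallelic(snp(100, alts=("G", "T")), {}, CFG)[0]
        assert not filter_qual_biallelic(snp(100, alts=("GT",)), {}, CFG)[0]
        assert not filter_qual_biallelic(snp(100, ref="AT", alts=("A",)), {}, CFG)[0]

    @pytest.mark.parametrize(
        "indel_pos,expected",
        [(90, True), (104, False), (96, False), (105, True), (95, True), (100, False)],
    )
    def test_indel_proximity_within_four_bases(self, indel_pos, expected):
        # |site - indel| <= 4 fails; 5 or more passes
        indels = {"chr1": [indel_pos]}
        ok, reason = filter_qual_biallelic(snp(100), indels, CFG)
        assert ok is expected, reason

    def test_indel_positions_collected_from_call_set(self):
        sites = [snp(10), snp(20, ref="AT", alts=("A",)), snp(30, alts=("GTT",))]
        assert collect_indel_positions(sites) == {"chr1": [20, 30]}
        assert near_indel(snp(24), {"chr1": [20, 30]}, 4)
        assert not near_indel(snp(25), {"chr1": [20, 30]}, 4)


class TestDepthStage:
    def test_exactly_at_limit_passes(self):
        site = site_from_depths("chr1", 1, [(750, 750)])
        assert filter_max_depth(site, CFG)  # total 1500

    def test_one_over_limit_fails(self):
        site = site_from_depths("chr1", 1, [(750, 751)])
        assert not filter_max_depth(site, CFG)

    def test_zero_depth_passes_depth_filter(self):
        assert filter_max_depth(site_from_depths("chr1", 1, [(0, 0)]), CFG)


class TestGenotypeRule:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (1, 2, Genotype.HET),  # the minimal supported heterozygote
            (0, 1, Genotype.MISSING),
            (10, 0, Genotype.HOM_REF),
            (0, 2, Genotype.HOM_ALT),
            (1, 0, Genotype.MISSING),  # one ref read cannot call hom_ref
            (2, 1, Genotype.MISSING),  # stray alt read spoils hom_ref
            (0, 0, Genotype.MISSING),
            (5, 5, Genotype.HET),
        ],
    )
    def test_read_support_rule(self, ref, alt, expected):
        assert call_genotype(SampleCall(ref_reads=ref, alt_reads=alt), CFG) is expected

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.integers(0, 100), st.integers(0, 100))
    def test_rule_is_total_and_consistent(self, ref, alt):
        g = call_genotype(SampleCall(ref_reads=ref, alt_reads=alt), CFG)
        assert g in set(Genotype)
        if g is Genotype.HET:
            assert alt >= 2 and ref >= 1
        if g is Genotype.HOM_REF:
            assert ref >= 2 and alt == 0
        if g is Genotype.HOM_ALT:
            assert alt >= 2 and ref == 0

    def test_without_allelic_depths_caller_genotype_is_kept(self):
        call = SampleCall(genotype=Genotype.HET, depth=20)
        assert call_genotype(call, CFG) is Genotype.HET


class TestMinSamplesStage:
    @pytest.mark.parametrize("n_called,expected", [(58, True), (57, False), (61, True), (0, False)])
    def test_callable_sample_threshold(self, n_called, expected):
        calls = [SampleCall(ref_reads=5, alt_reads=5) for _ in range(n_called)]
        calls += [SampleCall(ref_reads=0, alt_reads=0) for _ in range(61 - n_called)]
        site = VariantSite("chr1", 1, "A", ["G"], 50.0, calls)
        from paralogsift.site_filters import recall_genotypes

        recall_genotypes(site, CFG)
        assert filter_min_samples(site, CFG) is expected

    def test_default_scales_with_panel_size(self):
        assert CFG.resolved_min_samples(61) == 58
        assert CFG.resolved_min_samples(20) == 19


# ---------------------------------------------------------------------------
# DUST-style masking


def brute_force_dust(seq: str, cfg: FilterConfig) -> set[int]:
    """Independent window scorer: dict-counted triplets per window."""
    masked: set[int] = set()
    seq = seq.upper()
    segments, start = [], 0
    i = 0
    while i < len(seq):
        if seq[i] == "N":
            j = i
            while j < len(seq) and seq[j] == "N":
                j += 1
            if i > start:
                segments.append((start, i))
            masked.update(range(i, j))
            start = j
            i = j
        else:
            i += 1
    if len(seq) > start:
        segments.append((start, len(seq)))
    for s0, s1 in segments:
        if s1 - s0 < 3:
            continue
        win = min(cfg.dust_window, s1 - s0)
        norm = max(win - 3, 1)
        for ws in range(s0, s1 - win + 1):
            counts: dict[str, int] = {}
            for k in range(ws, ws + win - 2):
                t = seq[k : k + 3]
                counts[t] = counts.get(t, 0) + 1
            score = sum(c * (c - 1) // 2 for c in counts.values()) / norm
            if score > cfg.dust_threshold:
                masked.update(range(ws, ws + win))
    return masked


def mask_positions(regions) -> set[int]:
    out: set[int] = set()
    for r in regions:
        out.update(range(r.start, r.end))
    return out


def de_bruijn_acgt3() -> str:
    """Cyclic sequence containing each of the 64 trinucleotides once."""
    k, n = 4, 3
    a = [0] * k * n
    seq: list[int] = []

    def db(t, p):
        if t > n:
            if n % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, k):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    return "".join("ACGT"[i] for i in seq)


class TestDustMask:
    def test_homopolymer_fully_masked(self):
        regions = dust_mask("A" * 64, CFG)
        assert mask_positions(regions) == set(range(64))

    def test_dinucleotide_repeat_fully_masked(self):
        regions = dust_mask("AC" * 32, CFG)
        assert mask_positions(regions) == set(range(64))

    def test_maximally_diverse_window_not_masked(self):
        # 64 bases of a de Bruijn cycle: every trinucleotide distinct, score 0
        seq = de_bruijn_acgt3()[:64]
        assert dust_mask(seq, CFG) == []

    def test_window_below_three_rejected(self):
        with pytest.raises(ValueError):
            dust_mask("ACGT", FilterConfig(dust_window=2))

    def test_matches_brute_force_on_random_corpus(self):
        rng = np.random.default_rng(5)
        corpus = []
        for length in [3, 10, 63, 64, 65, 120, 200]:
            corpus.append("".join(rng.choice(list("ACGT"), size=length)))
        # structured strings: repeats embedded in random background, N runs
        bg = "".join(rng.choice(list("ACGT"), size=200))
        corpus.append(bg[:80] + "T" * 40 + bg[120:])
        corpus.append(bg[:50] + "AG" * 35 + bg[120:])
        corpus.append(bg[:90] + "N" * 15 + bg[105:])
        corpus.append("N" * 10)
        for seq in corpus:
            expected = brute_force_dust(seq, CFG)
            got = mask_positions(dust_mask(seq, CFG))
            assert got == expected, f"mismatch on {seq[:30]}..."


# ---------------------------------------------------------------------------
# Cascade


def toy_panel():
    """10 SNPs over 4 samples with one designed violation of each stage."""
    sheet = make_sheet(3, 1)
    cfg = FilterConfig(min_samples=3, max_depth=1500)
    good = [(10, 10)] * 4
    sites = [
        site_from_depths("chr1", 100, good),
        site_from_depths("chr1", 200, good, qual=25.0),  # QUAL violation
        site_from_depths("chr1", 300, good),
        site_from_depths("chr1", 405, good),  # LC violation (mask below)
        site_from_depths("chr1", 500, good),
        site_from_depths("chr1", 600, [(400, 400), (400, 301), (0, 0), (0, 0)]),  # DP: 1501
        site_from_depths("chr1", 700, good),
        site_from_depths("chr1", 800, [(10, 10), (10, 10), (0, 1), (1, 0)]),  # NS: 2 callable
        site_from_depths("chr1", 900, good),
        site_from_depths("chr1", 1000, good),
    ]
    masks = [MaskRegion("chr1", 400, 410)]
    return sites, masks, cfg, sheet


class TestCascade:
    def test_empty_input(self):
        survivors, ledger = apply_filter_cascade([], [], CFG, make_sheet(1, 1))
        assert survivors == []
        assert all(v == 0 for v in ledger.entering.values())

    def test_toy_panel_losses_named_per_stage(self):
        sites, masks, cfg, sheet = toy_panel()
        survivors, ledger = apply_filter_cascade(sites, masks, cfg, sheet)
        assert [s.pos for s in survivors] == [100, 300, 500, 700, 900, 1000]
        assert ledger.removed == {"QUAL": 1, "LC": 1, "DP": 1, "NS": 1}
        assert ledger.entering["QUAL"] == 10
        assert ledger.passing["NS"] == 6

    def test_survivor_counts_non_increasing_across_stages(self, default_sim):
        res = default_sim
        _, ledger = apply_filter_cascade(
            list(res.callset_a), [], FilterConfig(), res.sheet
        )
        values = [ledger.entering["QUAL"]] + [ledger.passing[s] for s in ("QUAL", "LC", "DP", "NS")]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_surviving_set_invariant_under_stage_order(self):
        sites, masks, cfg, sheet = toy_panel()
        from paralogsift.site_filters import (
            MaskIndex,
            collect_indel_positions,
            recall_genotypes,
        )

        indels = collect_indel_positions(sites)
        index = MaskIndex(masks)
        for s in sites:
            recall_genotypes(s, cfg)
        predicates = {
            "QUAL": lambda s: filter_qual_biallelic(s, indels, cfg)[0],
            "LC": lambda s: not index.contains(s.chrom, s.pos),
            "DP": lambda s: filter_max_depth(s, cfg),
            "NS": lambda s: filter_min_samples(s, cfg),
        }
        reference = None
        for order in itertools.permutations(predicates):
            surviving = [s for s in sites if all(predicates[k](s) for k in order)]
            keys = {s.key for s in surviving}
            if reference is None:
                reference = keys
            assert keys == reference

    def test_near_indel_snp_removed_when_indel_in_call_set(self):
        sheet = make_sheet(3, 1)
        cfg = FilterConfig(min_samples=3)
        good = [(10, 10)] * 4
        indel = VariantSite("chr1", 203, "AT", ["A"], 90.0,
                            [SampleCall(10, 0) for _ in range(4)])
        sites = [site_from_depths("chr1", 100, good),
                 site_from_depths("chr1", 200, good), indel]
        survivors, ledger = apply_filter_cascade(sites, [], cfg, sheet)
        # the indel itself and the SNP 3 bp away both leave at the QUAL stage
        assert [s.pos for s in survivors] == [100]
        assert ledger.removed["QUAL"] == 2
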