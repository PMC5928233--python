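"""Doubled-haploid screen, exact Hardy-Weinberg test, threshold sweep and
arm-level density."""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pytest

from paralogsift.duplication import (
    PsvClassification,
    arm_density,
    classify_psv,
    dh_het_count,
    dh_screen,
    hwe_exact_test,
    mean_observed_heterozygosity,
    observed_heterozygosity,
    threshold_sweep,
)
from paralogsift.model import Arm, GenomeBuild
from conftest import make_sheet, site_from_genotypes


class TestDhHetCount:
    # sheet: 4 outbred then 3 DH samples
    sheet = make_sheet(4, 3)

    def test_no_dh_hets(self):
        site = site_from_genotypes("chr1", 1, "1111000")
        assert dh_het_count(site, self.sheet) == 0

    def test_counts_only_dh_hets(self):
        site = site_from_genotypes("chr1", 1, "0000110")
        assert dh_het_count(site, self.sheet) == 2

    def test_missing_dh_genotypes_do_not_count(self):
        site = site_from_genotypes("chr1", 1, "1111...")
        assert dh_het_count(site, self.sheet) == 0

    @pytest.mark.parametrize(
        "gts,threshold,expected",
        [
            ("0000100", 2, PsvClassification.RETAINED_SNP),  # one DH het
            ("0000110", 2, PsvClassification.PUTATIVE_PSV_MSV),
            ("0000100", 1, PsvClassification.PUTATIVE_PSV_MSV),
        ],
    )
    def test_classification_threshold(self, gts, threshold, expected):
        site = site_from_genotypes("chr1", 1, gts)
        assert classify_psv(site, self.sheet, threshold=threshold) is expected


# ---------------------------------------------------------------------------
# Exact HWE test vs exact-rational enumeration


@lru_cache(maxsize=None)
def _hwe_distribution(n: int, n_a: int) -> tuple[tuple[int, Fraction], ...]:
    """Exact distribution of the heterozygote count given n samples and n_a
    reference alleles, by direct Fraction arithmetic."""
    n_b = 2 * n - n_a
    out = []
    for h in range(min(n_a, n_b) + 1):
        if (n_a - h) % 2:
            continue
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        num = math.factorial(n) * 2**h * math.factorial(n_a) * math.factorial(n_b)
        den = (
            math.factorial(aa) * math.factorial(h) * math.factorial(bb)
            * math.factorial(2 * n)
        )
        out.append((h, Fraction(num, den)))
    return tuple(out)


def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Independent enumeration with exact Fraction arithmetic."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    dist = dict(_hwe_distribution(n, n_a))
    p_obs = dist[n_ab]
    total = sum(p for p in dist.values() if p <= p_obs)
    return float(min(total, 1))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_extreme_heterozygote_excess(self):
        assert hwe_exact_test(0, 50, 0) < 1e-6

    def test_balanced_table_matches_enumeration(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(hwe_oracle(25, 50, 25), rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_exhaustive_small_tables(self):
        for n in range(1, 41):
            for n_ab in range(n + 1):
                for n_aa in range(n - n_ab + 1):
                    n_bb = n - n_ab - n_aa
                    p = hwe_exact_test(n_aa, n_ab, n_bb)
                    assert 0.0 <= p <= 1.0
                    assert p == pytest.approx(hwe_oracle(n_aa, n_ab, n_bb), rel=1e-8)

    def test_random_tables_up_to_two_hundred(self):
        rng = np.random.default_rng(31)
        for n in range(41, 201, 1):
            for _ in range(2):
                n_ab = int(rng.integers(0, n + 1))
                n_aa = int(rng.integers(0, n - n_ab + 1))
                n_bb = n - n_ab - n_aa
                p = hwe_exact_test(n_aa, n_ab, n_bb)
                assert p == pytest.approx(hwe_oracle(n_aa, n_ab, n_bb), rel=1e-8)


class TestObservedHeterozygosity:
    sheet = make_sheet(4, 2)

    def test_all_het(self):
        site = site_from_genotypes("chr1", 1, "111100")
        assert observed_heterozygosity(site, self.sheet.non_dh_indices) == 1.0

    def test_no_het(self):
        site = site_from_genotypes("chr1", 1, "002200")
        assert observed_heterozygosity(site, self.sheet.non_dh_indices) == 0.0

    def test_missing_excluded_from_denominator(self):
        site = site_from_genotypes("chr1", 1, "01.200")
        # outbred calls: 0,1,.,2 -> 1 het of 3 called
        assert observed_heterozygosity(site, self.sheet.non_dh_indices) == pytest.approx(1 / 3)

    def test_mean_over_sites(self):
        sites = [
            site_from_genotypes("chr1", 1, "110000"),
            site_from_genotypes("chr1", 2, "111100"),
        ]
        assert mean_observed_heterozygosity(sites, self.sheet.non_dh_indices) == pytest.approx(0.75)


class TestThresholdSweep:
    def test_threshold_beyond_dh_count_flags_nothing(self):
        sheet = make_sheet(4, 3)
        sites = [site_from_genotypes("chr1", 1, "0000111")]
        rows = threshold_sweep(sites, sheet, thresholds=[4])
        assert rows[0].n_flagged == 0

    def test_hand_built_panel(self):
        # 4 outbred + 3 DH; five sites with DH het counts 0,1,2,3,3
        sheet = make_sheet(4, 3)
        sites = [
            site_from_genotypes("chr1", 1, "0110000"),  # outbred Ho 0.5
            site_from_genotypes("chr1", 2, "0110100"),  # Ho 0.5
            site_from_genotypes("chr1", 3, "1111110"),  # Ho 1.0
            site_from_genotypes("chr1", 4, "1111111"),  # Ho 1.0
            site_from_genotypes("chr1", 5, "0111111"),  # Ho 0.75
        ]
        rows = threshold_sweep(sites, sheet)
        assert [r.n_flagged for r in rows] == [4, 3, 2]
        assert rows[0].mean_outbred_ho == pytest.approx((0.5 + 1.0 + 1.0 + 0.75) / 4)
        assert rows[1].mean_outbred_ho == pytest.approx((1.0 + 1.0 + 0.75) / 3)
        assert rows[2].mean_outbred_ho == pytest.approx((1.0 + 0.75) / 2)
        assert rows[0].label == "Het > 0"
        assert rows[-1].label == "Het = 3"

    def test_flag_sets_nested_across_thresholds(self):
        rng = np.random.default_rng(13)
        sheet = make_sheet(10, 5)
        sites = [
            site_from_genotypes(
                "chr1", p, "".join("012."[int(g)] for g in rng.integers(0, 4, 15))
            )
            for p in range(1, 200)
        ]
        flagged_at = {
            k: {s.key for s in dh_screen(sites, sheet, threshold=k, compute_hwe=False)[1]}
            for k in range(1, 6)
        }
        for k in range(1, 5):
            assert flagged_at[k + 1] <= flagged_at[k]

    def test_screen_partitions_input(self):
        rng = np.random.default_rng(29)
        sheet = make_sheet(6, 4)
        sites = [
            site_from_genotypes(
                "chr1", p, "".join("012."[int(g)] for g in rng.integers(0, 4, 10))
            )
            for p in range(1, 100)
        ]
        retained, flagged, results = dh_screen(sites, sheet, compute_hwe=False)
        assert len(retained) + len(flagged) == len(sites)
        assert {s.key for s in retained}.isdisjoint({s.key for s in flagged})
        assert len(results) == len(sites)


class TestArmDensity:
    build = GenomeBuild(
        {"chr1": 200, "chr2": 200},
        arms=[
            Arm("chr1p", "chr1", 0, 100),
            Arm("chr1q", "chr1", 100, 200),
            Arm("chr2p", "chr2", 0, 100),
            Arm("chr2q", "chr2", 100, 200),
        ],
        duplicated_pairs=[("chr1q", "chr2p")],
    )

    def test_no_flagged_sites(self):
        rows = arm_density([], self.build)
        assert all(r.n_flagged == 0 for r in rows)
        assert {r.arm: r.is_delayed_rediploidization for r in rows} == {
            "chr1p": False, "chr1q": True, "chr2p": True, "chr2q": False,
        }

    def test_sites_assigned_to_correct_arm(self):
        sites = [
            site_from_genotypes("chr1", 100, "1"),  # last base of chr1p
            site_from_genotypes("chr1", 101, "1"),  # first base of chr1q
            site_from_genotypes("chr2", 150, "1"),
        ]
        rows = {r.arm: r.n_flagged for r in arm_density(sites, self.build)}
        assert rows == {"chr1p": 1, "chr1q": 1, "chr2p": 0, "chr2q": 1}

    def test_single_arm_holds_all(self):
        sites = [site_from_genotypes("chr1", p, "1") for p in (1, 50, 100)]
        rows = {r.arm: r.n_flagged for r in arm_density(sites, self.build)}
        assert rows["chr1p"] == 3
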