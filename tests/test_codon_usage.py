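"""Codon counting, RSCU, ENc, PR2 and neutrality-regression behaviour."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitocodon import (
    GeneticCode,
    INVERTEBRATE_MITO,
    CodonUsageTable,
    count_codons,
    enc,
    enc_expected,
    make_codon_set,
    neutrality_fit,
    pr2_point,
    rscu,
    third_position_composition,
)

CODE = INVERTEBRATE_MITO


class TestGeneticCode:
    def test_families_partition_all_sense_codons(self):
        codons = [c for fam in CODE.families.values() for c in fam]
        assert sorted(codons) == sorted(CODE.sense_codons)
        assert len(codons) == 62  # 64 - 2 stops under the invertebrate mito code

    def test_family_sizes_are_two_or_four(self):
        sizes = sorted(len(f) for f in CODE.families.values())
        assert set(sizes) == {2, 4}
        assert sizes.count(2) == 13 and sizes.count(4) == 9

    def test_leu_ser_split_convention(self):
        assert CODE.codon_to_family["CTA"] == "Leu1"  # CUN
        assert CODE.codon_to_family["TTA"] == "Leu2"  # UUR
        assert CODE.codon_to_family["AGA"] == "Ser1"  # AGN (AGR = Ser here)
        assert CODE.codon_to_family["TCA"] == "Ser2"  # UCN

    def test_mito_specific_assignments(self):
        assert CODE.codon_to_aa["ATA"] == "M"
        assert CODE.codon_to_aa["TGA"] == "W"
        assert CODE.stop_codons == frozenset({"TAA", "TAG"})


class TestCountCodons:
    def test_basic_with_stop(self):
        assert count_codons("ATGTTATAA") == Counter({"ATG": 1, "TTA": 1, "TAA": 1})

    def test_incomplete_stop_dropped(self):
        assert count_codons("ATGT") == Counter({"ATG": 1})

    def test_internal_stop_warns_with_position(self):
        with pytest.warns(UserWarning, match="codon 2"):
            count_codons("ATGTAATTA")

    def test_concatenated_total_matches_arithmetic(self, rng):
        # codon total over a concatenation equals sum of floor(len/3)
        genes = []
        for _ in range(13):
            n = int(rng.integers(40, 200))
            tail = int(rng.integers(0, 3))
            genes.append(make_codon_set(
                {c: 1 / 62 for c in CODE.sense_codons}, n, seed=int(rng.integers(2**31)),
            )[: 3 * n + tail])
        expected = sum(len(g) // 3 for g in genes)
        total = sum(sum(count_codons(g).values()) for g in genes)
        assert total == expected


class TestRscu:
    def test_single_codon_of_two_fold_family_forced_values(self):
        values = rscu({"TTA": 7})
        assert values["TTA"] == 2.0 and values["TTG"] == 0.0

    def test_uniform_four_fold_family(self):
        values = rscu({"GTA": 5, "GTC": 5, "GTG": 5, "GTT": 5})
        assert all(values[c] == 1.0 for c in ("GTA", "GTC", "GTG", "GTT"))

    def test_sampled_nine_to_one_profile(self):
        profile = {"TTA": 0.45, "TTG": 0.05, "GTT": 0.5}
        counts = count_codons(make_codon_set(profile, 1000, seed=3))
        with pytest.warns(UserWarning):
            values = rscu(counts)
        # p(TTA|Leu2) = 0.9 -> RSCU 1.8; 3 sigma of the binomial proportion
        sigma = 2 * math.sqrt(0.9 * 0.1 / 500)
        assert values["TTA"] == pytest.approx(1.8, abs=3 * sigma)

    def test_unused_family_flagged_as_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            values = rscu({"TTA": 3})
        assert math.isnan(values["GGA"])

    @given(
        st.dictionaries(
            st.sampled_from(sorted(CODE.sense_codons)),
            st.integers(min_value=0, max_value=50),
            min_size=1,
        )
    )
    def test_family_sums_equal_family_size(self, counts):
        values = rscu(counts)
        for label, codons in CODE.families.items():
            if sum(counts.get(c, 0) for c in codons) > 0:
                assert sum(values[c] for c in codons) == pytest.approx(len(codons))


class TestThirdPositionComposition:
    def test_all_third_a(self):
        comp = third_position_composition({"TTA": 4, "GGA": 6})
        assert comp.gc3 == 0.0
        assert pr2_point({"TTA": 4, "GGA": 6})[1] == 1.0

    def test_ggg_only(self):
        comp = third_position_composition({"GGG": 10})
        assert comp.gc3 == 100.0 and comp.gc12 == 100.0

    def test_gc3s_equals_gc3_under_split_convention(self):
        counts = count_codons(make_codon_set({c: 1 / 62 for c in CODE.sense_codons}, 500, seed=9))
        comp = third_position_composition(counts)
        assert comp.gc3s == pytest.approx(comp.gc3)

    def test_planted_gc3_recovered(self):
        gc_enders = [c for c in CODE.sense_codons if c[2] in "GC"]
        at_enders = [c for c in CODE.sense_codons if c[2] in "AT"]
        profile = {c: 0.05 / len(gc_enders) for c in gc_enders}
        profile.update({c: 0.95 / len(at_enders) for c in at_enders})
        counts = count_codons(make_codon_set(profile, 2000, seed=12))
        assert third_position_composition(counts).gc3 == pytest.approx(5.0, abs=1.0)


class TestEnc:
    def test_one_codon_per_family_gives_family_count(self):
        counts = {fam[0]: 10 for fam in CODE.families.values()}
        assert enc(counts) == pytest.approx(22.0)  # 13 + 9 families

    def test_uniform_usage_approaches_sum_of_family_sizes(self):
        counts = {c: 1000 for c in CODE.sense_codons}
        with pytest.warns(UserWarning, match="nominal maximum"):
            value = enc(counts)
        assert value == pytest.approx(62.0, abs=0.5)

    def test_profile_tuned_to_target_enc(self):
        # closed form at concentration w: F2 = w^2 + (1-w)^2,
        # F4 = w^2 + (1-w)^2 / 3; ENc(w) = 13/F2 + 9/F4. Bisect for 30.
        def enc_inf(w):
            return 13 / (w**2 + (1 - w) ** 2) + 9 / (w**2 + (1 - w) ** 2 / 3)

        lo, hi = 0.5, 1.0  # enc_inf is decreasing on [0.5, 1]
        for _ in range(60):
            mid = (lo + hi) / 2
            lo, hi = (lo, mid) if enc_inf(mid) < 30 else (mid, hi)
        w = (lo + hi) / 2
        profile = {}
        for fam in CODE.families.values():
            k = len(fam)
            profile[fam[0]] = w / 22
            for c in fam[1:]:
                profile[c] = (1 - w) / (k - 1) / 22
        counts = count_codons(make_codon_set(profile, 20000, seed=21))
        assert enc(counts) == pytest.approx(30.0, abs=1.0)

    def test_missing_degeneracy_class_imputed_with_warning(self):
        two_fold_only = {fam[0]: 5 for fam in CODE.families.values() if len(fam) == 2}
        two_fold_only.update({fam[1]: 5 for fam in CODE.families.values() if len(fam) == 2})
        with pytest.warns(UserWarning, match="degeneracy 4"):
            value = enc(two_fold_only)
        assert value > 0

    @pytest.mark.parametrize("concentration", [0.25, 0.4, 0.6, 0.9])
    def test_monotone_in_family_concentration(self, concentration):
        # concentrating one 4-fold family lowers ENc relative to uniform
        base = {c: 1200 for c in CODE.sense_codons}
        fam = CODE.families["Val"]
        n = 4 * 1200
        skewed = dict(base)
        skewed[fam[0]] = round(n * concentration)
        rest = (n - skewed[fam[0]]) // 3
        for c in fam[1:]:
            skewed[c] = rest
        if concentration > 0.25:
            assert enc(skewed) < enc(base)
        else:
            assert enc(skewed) == pytest.approx(enc(base), abs=0.05)


class TestEncExpected:
    @pytest.mark.parametrize("gc3s,expected", [(0.0, 31.0), (0.5, 60.5), (1.0, 32.0)])
    def test_printed_formula_values(self, gc3s, expected):
        assert enc_expected(gc3s) == pytest.approx(expected)

    @given(st.floats(min_value=0, max_value=1))
    def test_symmetric_up_to_linear_term(self, s):
        # the homozygosity denominator is symmetric about 0.5; the +GC3s
        # term is the only asymmetric part of the curve
        assert enc_expected(s) - s == pytest.approx(enc_expected(1 - s) - (1 - s), abs=1e-9)

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            enc_expected(1.5)


class TestPr2:
    def test_balanced_third_positions_center(self):
        counts = {"TTA": 5, "TTT": 5, "GGG": 5, "GGC": 5}
        assert pr2_point(counts) == pytest.approx((0.5, 0.5))

    def test_no_g_but_some_c_gives_zero_abscissa(self):
        counts = {"GGC": 3, "TTA": 5, "TTT": 5}
        assert pr2_point(counts)[0] == 0.0

    def test_all_third_t_gives_zero_ordinate(self):
        counts = {"TTT": 4, "GGC": 2}
        x, y = pr2_point(counts)
        assert y == 0.0 and x == 0.0

    def test_no_g_and_no_c_flagged_undefined(self):
        with pytest.warns(UserWarning, match="abscissa undefined"):
            x, _ = pr2_point({"TTA": 4, "GGA": 2})
        assert math.isnan(x)

    def test_complement_swap_mirrors_coordinates(self):
        counts = {"TTA": 7, "TTT": 3, "GGG": 2, "GGC": 8}
        swapped = {"TTT": 7, "TTA": 3, "GGC": 2, "GGG": 8}
        x, y = pr2_point(counts)
        xs, ys = pr2_point(swapped)
        assert (xs, ys) == pytest.approx((1 - x, 1 - y))


class TestNeutralityFit:
    def test_points_on_diagonal(self):
        fit = neutrality_fit([(1, 1), (2, 2), (3, 3), (4, 4)])
        assert fit.slope == pytest.approx(1.0) and fit.r2 == pytest.approx(1.0)

    def test_constant_gc12(self):
        fit = neutrality_fit([(1, 5), (2, 5), (3, 5)])
        assert fit.slope == 0.0 and fit.r2 == 0.0

    def test_zero_gc3_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            fit = neutrality_fit([(2, 1), (2, 5), (2, 3)])
        assert math.isnan(fit.slope)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            neutrality_fit([(1, 1), (2, 2)])

    def test_planted_slope_recovered_within_two_se(self):
        rng = np.random.default_rng(77)
        slope, sigma, n = -0.9, 1.5, 12
        x = rng.uniform(3, 15, n)
        y = 20 + slope * x + rng.normal(0, sigma, n)
        fit = neutrality_fit(list(zip(x, y)))
        se = sigma / math.sqrt(((x - x.mean()) ** 2).sum())
        assert fit.slope == pytest.approx(slope, abs=2 * se)


class TestCodonUsageTable:
    def test_integration_from_sampled_cds(self):
        profile = {c: 1 / 62 for c in CODE.sense_codons}
        table = CodonUsageTable.from_cds("g", make_codon_set(profile, 3000, seed=5))
        assert table.n_codons_used == 62
        assert sum(table.aa_freq.values()) == pytest.approx(100.0)
        assert 0 <= table.pr2_x <= 1 and 0 <= table.pr2_y <= 1

    def test_codons_used_counts_only_observed(self):
        table = CodonUsageTable.from_cds("g", "ATGTTATTATAA")
        assert table.n_codons_used == 2  # ATG and TTA
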