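"""XCI quantification: ratios, stutter, classification, population statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xcistr.exceptions import (
    EstimationError,
    InputError,
    InsufficientDataError,
    MendelianInconsistencyError,
)
from xcistr.xci import (
    StutterModel,
    allelic_span,
    build_result,
    classify_skewing,
    combined_informativeness,
    compute_xci_ratio,
    concordance,
    correct_stutter,
    digestion_qc,
    digestion_qc_batch,
    estimate_stutter_fraction,
    phase_trio,
    population_stats,
)

from _oracles import spearman_manual

GAAA_MODEL = StutterModel("RP2", 4, 0.026)


def _peaks(rows):
    return pd.DataFrame(
        rows, columns=["sample", "locus", "treatment", "allele_size", "area", "height"]
    )


class TestStutterEstimation:
    def test_hemizygous_ratio_arithmetic(self):
        rows = []
        for i, (true, st_area) in enumerate([(10000, 260), (8000, 208), (4000, 104)]):
            rows.append((f"M{i}", "RP2", "undigested", 368.0, true, true / 20))
            rows.append((f"M{i}", "RP2", "undigested", 364.0, st_area, st_area / 20))
        assert estimate_stutter_fraction(_peaks(rows), "RP2", 4) == pytest.approx(0.026)

    def test_absent_stutter_contributes_zero(self):
        rows = [("M0", "RP2", "undigested", 368.0, 10000, 500)]
        assert estimate_stutter_fraction(_peaks(rows), "RP2", 4) == 0.0

    def test_no_single_allele_samples_is_estimation_error(self):
        rows = [
            ("F0", "RP2", "undigested", 368.0, 10000, 500),
            ("F0", "RP2", "undigested", 352.0, 9000, 450),
        ]
        with pytest.raises(EstimationError):
            estimate_stutter_fraction(_peaks(rows), "RP2", 4)


class TestStutterCorrection:
    def test_one_unit_apart_subtracts_proportional_stutter(self):
        corrected, flags = correct_stutter([368, 364], [10000, 5260], GAAA_MODEL)
        assert corrected == [10000, 5000]
        assert flags == []
        # conservation: corrected + subtracted == observed
        assert corrected[1] + 0.026 * 10000 == pytest.approx(5260)

    def test_distant_alleles_unchanged(self):
        corrected, _ = correct_stutter([368, 352], [10000, 5260], GAAA_MODEL)
        assert corrected == [10000.0, 5260.0]

    def test_zero_fraction_is_identity(self):
        model = StutterModel("RP2", 4, 0.0)
        corrected, _ = correct_stutter([368, 364], [10000, 5260], model)
        assert corrected == [10000.0, 5260.0]

    def test_overcorrection_floors_at_zero_and_flags(self):
        corrected, flags = correct_stutter([368, 364], [10000, 100], GAAA_MODEL)
        assert corrected[1] == 0.0
        assert "stutter_overcorrection" in flags

    @given(
        long_area=st.floats(1000, 50000),
        short_area=st.floats(1000, 50000),
        fraction=st.floats(0, 0.3),
    )
    def test_conservation_property(self, long_area, short_area, fraction):
        model = StutterModel("RP2", 4, fraction)
        corrected, _ = correct_stutter([368, 364], [long_area, short_area], model)
        subtracted = short_area - corrected[1]
        if corrected[1] > 0:
            assert corrected[1] + subtracted == pytest.approx(short_area, rel=1e-9)


class TestXCIRatio:
    @pytest.mark.parametrize(
        "u,d,expected",
        [
            ((10000, 10000), (5000, 5000), 0.5),
            ((5000, 10000), (5000, 2000), 1.0 / 1.2),
            ((8000, 9000), (7900, 0), 1.0),
        ],
    )
    def test_stated_examples(self, u, d, expected):
        r, _ = compute_xci_ratio(u, d)
        assert r == pytest.approx(expected)

    def test_dropout_and_total_digestion_errors(self):
        with pytest.raises(InputError, match="dropout"):
            compute_xci_ratio((0, 10000), (5000, 5000))
        with pytest.raises(InputError, match="no_signal"):
            compute_xci_ratio((10000, 10000), (0, 0))

    @given(
        u1=st.floats(100, 1e5), u2=st.floats(100, 1e5),
        d1=st.floats(0, 1e5), d2=st.floats(1, 1e5),
    )
    def test_label_symmetry(self, u1, u2, d1, d2):
        r, _ = compute_xci_ratio((u1, u2), (d1, d2))
        r_swapped, _ = compute_xci_ratio((u2, u1), (d2, d1))
        assert r_swapped == pytest.approx(1 - r, abs=1e-12)

    @given(u1=st.floats(100, 1e5), u2=st.floats(100, 1e5))
    def test_normalization_identity(self, u1, u2):
        # digested == undigested -> balanced 0.5 regardless of amplification bias
        r, _ = compute_xci_ratio((u1, u2), (u1, u2))
        assert r == pytest.approx(0.5)


class TestSkewClassification:
    @pytest.mark.parametrize(
        "pct,expected",
        [(50, "random"), (65, "random"), (80, "random"),
         (80.5, "non_random"), (95, "non_random"), (100, "non_random")],
    )
    def test_band_boundaries(self, pct, expected):
        assert classify_skewing(pct) == expected

    def test_below_fifty_rejected(self):
        with pytest.raises(InputError):
            classify_skewing(42)

    def test_extreme_skew_flag_at_90(self):
        res = build_result("F1", "RP2", "HpaII", (352, 368), 0.92)
        assert res.skew_class == "non_random"
        assert "extremely_skewed" in res.qc
        res2 = build_result("F1", "RP2", "HpaII", (352, 368), 0.85)
        assert "extremely_skewed" not in res2.qc

    def test_main_inactive_pct_folds_to_major_allele(self):
        for r in (0.25, 0.75):
            res = build_result("F1", "RP2", "HpaII", (352, 368), r)
            assert res.main_inactive_pct == pytest.approx(75.0)
            assert res.xi_fraction_allele2 == pytest.approx(1 - r)


class TestDigestionQC:
    def test_thresholds(self):
        assert digestion_qc(10000, 0)
        assert digestion_qc(10000, 400)       # residual 4 % passes
        assert not digestion_qc(10000, 1000)  # residual 10 % fails

    def test_missing_undigested_companion(self):
        with pytest.raises(InputError):
            digestion_qc(0, 10)

    def test_all_female_batch_skips_with_warning(self):
        rows = [("F0", "RP2", "undigested", 368.0, 10000, 500)]
        with pytest.warns(UserWarning, match="skipped"):
            assert digestion_qc_batch(_peaks(rows), ["M9"], "RP2", "HpaII") is None


class TestPopulationStats:
    def _genotypes(self, pairs, locus="RP2"):
        rows = []
        for i, (a1, a2) in enumerate(pairs):
            rows.append({"sample": f"F{i}", "locus": locus, "sex": "F",
                         "allele1": a1, "allele2": a2})
        return pd.DataFrame(rows)

    def test_observed_heterozygosity_is_direct_count(self):
        pairs = [(352, 368)] * 5 + [(352, 352)] * 9  # 5 het of 14 females
        stats = population_stats(self._genotypes(pairs), "RP2")
        assert stats.n_typed == 14 and stats.n_heterozygous == 5
        assert stats.observed_heterozygosity == pytest.approx(5 / 14)
        assert sum(stats.allele_frequencies.values()) == pytest.approx(1.0)

    def test_all_homozygous_is_zero(self):
        stats = population_stats(self._genotypes([(352, 352)] * 8), "RP2")
        assert stats.observed_heterozygosity == 0.0

    def test_no_females_is_error(self):
        df = pd.DataFrame([{"sample": "M0", "locus": "RP2", "sex": "M",
                            "allele1": 352, "allele2": 352}])
        with pytest.raises(EstimationError):
            population_stats(df, "RP2")

    def test_biallelic_expected_heterozygosity_ceiling(self):
        # 2p(1-p) maximised over p on a fine grid -> 0.5 at p = 0.5
        p = np.linspace(0.001, 0.999, 999)
        he = 2 * p * (1 - p)
        assert he.max() == pytest.approx(0.5)
        assert p[he.argmax()] == pytest.approx(0.5)


class TestInformativeness:
    def test_independence_mode_printed_subsets(self):
        # per-subset heterozygosity pairs, equal-weight average
        value = combined_informativeness(
            [{"RP2": 0.85, "AR": 0.85}, {"RP2": 0.73, "AR": 0.87}],
            mode="independence",
        )
        assert round(value, 2) == 0.97

    def test_single_locus_degenerates_to_h(self):
        assert combined_informativeness([{"RP2": 0.85}]) == pytest.approx(0.85)

    def test_empirical_mode_counts_samples(self):
        rows = []
        for i in range(10):
            het_a = i < 8  # 8 of 10 heterozygous at A
            rows.append({"sample": f"F{i}", "locus": "A", "sex": "F",
                         "allele1": 1, "allele2": 2 if het_a else 1})
            rows.append({"sample": f"F{i}", "locus": "B", "sex": "F",
                         "allele1": 1, "allele2": 2 if i < 5 else 1})
        df = pd.DataFrame(rows)
        # het at >=1 locus: i<8 via A, i in {8,9} not het at B either -> 0.8
        assert combined_informativeness(df, mode="empirical") == pytest.approx(0.8)

    def test_empirical_all_het_at_one_locus_is_one(self):
        rows = []
        for i in range(6):
            rows.append({"sample": f"F{i}", "locus": "A", "sex": "F",
                         "allele1": 1, "allele2": 2})
            rows.append({"sample": f"F{i}", "locus": "B", "sex": "F",
                         "allele1": 1, "allele2": 1})
        assert combined_informativeness(pd.DataFrame(rows), "empirical") == 1.0

    def test_empirical_mismatched_samples_rejected(self):
        rows = [
            {"sample": "F0", "locus": "A", "sex": "F", "allele1": 1, "allele2": 2},
            {"sample": "F1", "locus": "B", "sex": "F", "allele1": 1, "allele2": 2},
        ]
        with pytest.raises(InputError):
            combined_informativeness(pd.DataFrame(rows), "empirical")


class TestConcordance:
    def test_identical_and_reversed_ranks(self):
        v = [50.0, 60, 70, 80, 90]
        assert concordance(v, v).spearman_r == pytest.approx(1.0)
        assert concordance(v, v[::-1]).spearman_r == pytest.approx(-1.0)

    def test_matches_manual_rank_formula(self, rng):
        x = rng.uniform(50, 100, 10)
        y = x + rng.normal(0, 5, 10)
        res = concordance(x, y)
        assert res.spearman_r == pytest.approx(spearman_manual(x, y), abs=1e-12)
        assert res.ci95[0] <= res.spearman_r <= res.ci95[1]

    def test_fisher_z_interval_width(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(50, 100, 30)
        y = x + rng.normal(0, 8, 30)
        res = concordance(x, y)
        z = np.arctanh(res.spearman_r)
        hw = 1.96 / np.sqrt(30 - 3)
        assert res.ci95 == (pytest.approx(np.tanh(z - hw)),
                            pytest.approx(np.tanh(z + hw)))

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            concordance([50, 60], [50, 60])


class TestTrioPhasing:
    def test_maternal_origin(self):
        assert phase_trio([368, 350], [340], [368, 340], 368) == "maternal"

    def test_paternal_origin(self):
        assert phase_trio([350, 352], [368], [350, 368], 368) == "paternal"

    def test_shared_allele_is_ambiguous(self):
        assert phase_trio([368, 350], [368], [368, 368], 368) == "ambiguous"

    def test_allele_absent_from_both_parents(self):
        with pytest.raises(MendelianInconsistencyError):
            phase_trio([350, 352], [340], [368, 340], 368)

    def test_father_must_be_hemizygous(self):
        with pytest.raises(InputError):
            phase_trio([350, 352], [340, 344], [350, 340], 350)


def test_allelic_span_of_printed_amplimer_range():
    # longest minus shortest allele: 391 - 350
    assert allelic_span([350.0, 362.0, 374.0, 391.0]) == 41.0
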