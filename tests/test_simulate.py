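"""Synthetic genome and cohort generators: determinism, truth recovery, HWE."""

import numpy as np
import pandas as pd
import pytest

from xcistr.exceptions import InputError
from xcistr.annotation import detect_cpg_islands, scan_restriction_sites
from xcistr.repeats import RepeatScanParams, find_tandem_repeats
from xcistr.simulate import (
    AR_LOCUS,
    RP2_LOCUS,
    CohortSpec,
    LocusPlan,
    PlantedCGI,
    PlantedRepeat,
    PlantedSite,
    SkewModel,
    SyntheticGenomeSpec,
    build_synthetic_genome,
    locus_grid_spec,
    simulate_biallelic_population,
    simulate_cohort,
)
from xcistr.xci import population_stats, quantify_cohort


class TestGenomeGenerator:
    def test_same_seed_is_bit_identical(self):
        spec = locus_grid_spec([LocusPlan("a"), LocusPlan("b", copies=11)], seed=5)
        g1 = build_synthetic_genome(spec)
        g2 = build_synthetic_genome(spec)
        assert g1.seq == g2.seq
        assert g1.truth.equals(g2.truth)

    def test_background_is_cpg_free(self):
        spec = SyntheticGenomeSpec(length=20000, seed=1)
        g = build_synthetic_genome(spec)
        assert "CG" not in g.seq
        assert scan_restriction_sites(g.seq) == []
        assert detect_cpg_islands(g.seq) == []

    def test_planted_features_recovered_by_detectors(self):
        spec = locus_grid_spec([LocusPlan("main")], seed=9)
        g = build_synthetic_genome(spec)
        truth = {row["name"]: row for _, row in g.truth.iterrows()}
        # repeat recovered within a few bp of in-phase flank slack
        reps = find_tandem_repeats(
            g.seq, RepeatScanParams(min_period=4, max_period=5,
                                    min_copy_number=12, min_match_pct=90))
        assert len(reps) == 1
        assert abs(reps[0].interval.start - truth["main"]["start"]) <= 4
        assert abs(reps[0].interval.end - truth["main"]["end"]) <= 4
        assert reps[0].unit == "GAAA"
        # CpG island recovered around its planted block
        islands = detect_cpg_islands(g.seq, chrom=g.spec.chrom)
        assert len(islands) == 1
        cgi_truth = truth["main_cgi"]
        assert islands[0].interval.overlaps(g.cgis[0].interval)
        assert abs(islands[0].interval.start - cgi_truth["start"]) <= 200
        # the planted HpaII site is found at its exact coordinate
        sites = scan_restriction_sites(g.seq)
        site_truth = truth["HpaII:main"]
        assert any(
            s.enzyme == "HpaII" and s.interval.start == site_truth["start"]
            for s in sites
        )

    def test_overlapping_planted_features_rejected(self):
        spec = SyntheticGenomeSpec(
            length=5000,
            repeats=(PlantedRepeat("r1", "GAAA", 16, 1000),
                     PlantedRepeat("r2", "CAG", 20, 1030)),
            seed=0,
        )
        with pytest.raises(InputError, match="overlap"):
            build_synthetic_genome(spec)

    def test_out_of_bounds_feature_rejected(self):
        spec = SyntheticGenomeSpec(
            length=100, repeats=(PlantedRepeat("r1", "GAAA", 30, 50),), seed=0
        )
        with pytest.raises(InputError, match="bounds"):
            build_synthetic_genome(spec)

    def test_written_tracks_round_trip(self, tmp_path):
        from xcistr.io import read_bed, read_fasta, read_gff3

        g = build_synthetic_genome(locus_grid_spec([LocusPlan("x")], seed=2))
        paths = g.write(tmp_path)
        seqs = read_fasta(paths["fasta"])
        assert seqs[g.spec.chrom] == g.seq
        cgi = read_bed(paths["cgi"])
        assert [(c.start, c.end) for c in cgi] == [
            (c.interval.start, c.interval.end) for c in g.cgis
        ]
        genes = read_gff3(paths["gff3"])
        assert [gm.gene_id for gm in genes] == [gm.gene_id for gm in g.genes]
        assert [gm.interval for gm in genes] == [gm.interval for gm in g.genes]
        assert [gm.exons for gm in genes] == [gm.exons for gm in g.genes]


class TestCohortGenerator:
    def test_same_seed_same_tables(self):
        spec = CohortSpec(n_females=10, n_males=2, seed=4)
        c1, c2 = simulate_cohort(spec), simulate_cohort(spec)
        assert c1.peaks.equals(c2.peaks)
        assert c1.genotypes.equals(c2.genotypes)

    def test_noise_free_closed_loop_returns_planted_skew_exactly(self):
        spec = CohortSpec(n_females=25, skew=SkewModel(fixed=0.8),
                          area_cv=0.0, seed=6)
        c = simulate_cohort(spec)
        res = quantify_cohort(c.peaks, "HpaII")
        merged = res.merge(c.truth, on=["sample", "locus"], suffixes=("", "_t"))
        assert len(merged) > 0
        assert np.allclose(
            merged["xi_fraction_allele1"], merged["xi_fraction_allele1_t"]
        )
        assert np.allclose(merged["main_inactive_pct"], 80.0)

    def test_male_digested_signal_absent_under_full_efficiency(self):
        spec = CohortSpec(n_females=0, n_males=5, digestion_efficiency=1.0,
                          area_cv=0.0, seed=1)
        peaks = simulate_cohort(spec).peaks
        assert peaks[peaks["treatment"] == "HpaII"].empty
        assert not peaks[peaks["treatment"] == "undigested"].empty

    def test_partial_digestion_shifts_ratio_toward_half(self):
        exact = CohortSpec(n_females=30, skew=SkewModel(fixed=0.9),
                           area_cv=0.0, seed=8)
        leaky = CohortSpec(n_females=30, skew=SkewModel(fixed=0.9),
                           digestion_efficiency=0.7, area_cv=0.0, seed=8)
        r_exact = quantify_cohort(simulate_cohort(exact).peaks, "HpaII")
        r_leaky = quantify_cohort(simulate_cohort(leaky).peaks, "HpaII")
        assert (r_leaky["main_inactive_pct"].mean()
                < r_exact["main_inactive_pct"].mean())
        # incomplete digestion: ratio = xi + (1-xi)(1-e) over total retained
        expected = (0.9 + 0.1 * 0.3) / (0.9 + 0.1 * 0.3 + 0.1 + 0.9 * 0.3)
        assert r_leaky["main_inactive_pct"].max() == pytest.approx(
            100 * expected, abs=1e-6)

    def test_stutter_peaks_sit_one_unit_below_true_alleles(self):
        spec = CohortSpec(n_females=0, n_males=3, loci=(RP2_LOCUS,),
                          area_cv=0.0, seed=2)
        peaks = simulate_cohort(spec).peaks
        und = peaks[peaks["treatment"] == "undigested"]
        for _, grp in und.groupby("sample"):
            grp = grp.sort_values("area", ascending=False)
            true_size = grp.iloc[0]["allele_size"]
            stutter = grp.iloc[1:]
            assert (stutter["allele_size"] == true_size - 4).all()
            assert stutter["area"].sum() == pytest.approx(
                0.026 * grp.iloc[0]["area"])

    def test_monomorphic_locus_yields_no_heterozygotes(self):
        mono = RP2_LOCUS.__class__("mono", 4, (368.0,), (1.0,), 0.026)
        spec = CohortSpec(n_females=10, loci=(mono,), seed=3)
        c = simulate_cohort(spec)
        stats = population_stats(c.genotypes, "mono")
        assert stats.observed_heterozygosity == 0.0


class TestBiallelicPopulation:
    def test_hwe_heterozygosity_matches_closed_form(self):
        df = simulate_biallelic_population(p=0.22, n=10000, seed=13)
        stats = population_stats(df, "RP2_marmoset")
        assert stats.observed_heterozygosity == pytest.approx(
            2 * 0.22 * 0.78, abs=0.02)

    def test_half_frequency_approaches_ceiling(self):
        df = simulate_biallelic_population(p=0.5, n=20000, seed=13)
        stats = population_stats(df, "RP2_marmoset")
        assert stats.observed_heterozygosity == pytest.approx(0.5, abs=0.02)
        assert stats.expected_heterozygosity == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_frequencies_rejected(self, p):
        with pytest.raises(InputError):
            simulate_biallelic_population(p=p, n=10, seed=0)
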