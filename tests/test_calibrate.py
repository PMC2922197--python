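"""Read simulation, the efficiency model and factor calibration."""

import math

import numpy as np
import pytest

from spsr.calibrate import (
    EfficiencyModel,
    FactorTable,
    asymptotic_factors,
    calibrate_pooled,
    compute_raw_factors,
    normalize_factors,
    relative_efficiency,
    simulate_reads,
    total_efficiency,
    train_superorganisms,
)


class TestSimulateReads:
    def test_read_count_from_coverage(self):
        genome = "ACGT" * 2500  # 10 kb
        reads = simulate_reads(genome, 50, 5.0, seed=0)
        assert len(reads) == 1000
        assert all(r.length_nt == 50 for r in reads)

    def test_deterministic_under_seed(self):
        genome = "ACGT" * 300
        a = simulate_reads(genome, 50, 2.0, seed=42)
        b = simulate_reads(genome, 50, 2.0, seed=42)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_degenerate_coverage_emits_one_read(self):
        reads = simulate_reads("ACGT" * 25, 100, 0.001, seed=0)
        assert len(reads) == 1

    def test_read_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads("ACGT", 50, 1.0, seed=0)


class TestEfficiency:
    @pytest.mark.parametrize(
        "L,expected",
        [(17, 0.0), (1, 1.0), (9, 0.5), (16, 1 / 16), (7, 10 / 16)],
    )
    def test_50nt_formula(self, L, expected):
        # (17 - L)/16 for 50-nt reads, zero beyond the 16-residue window
        assert relative_efficiency(L, 50) == pytest.approx(expected)

    def test_short_read_rejected(self):
        with pytest.raises(ValueError):
            relative_efficiency(7, 2)

    def test_point_mass_total(self):
        model = EfficiencyModel({7: 1.0})
        assert total_efficiency(model, 50) == pytest.approx(10 / 16)

    def test_uniform_distribution_matches_direct_summation(self):
        Ls = list(range(7, 17))
        model = EfficiencyModel({L: 1 / len(Ls) for L in Ls})
        expected = sum((17 - L) / 16 for L in Ls) / len(Ls)
        assert total_efficiency(model, 50) == pytest.approx(expected)

    def test_monotone_in_read_length_with_unit_limit(self):
        model = EfficiencyModel({7: 0.3, 10: 0.4, 14: 0.3})
        effs = [total_efficiency(model, n) for n in (50, 100, 200, 400, 10_000)]
        assert all(a <= b for a, b in zip(effs, effs[1:]))
        assert effs[-1] == pytest.approx(1.0, abs=0.01)

    def test_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError):
            EfficiencyModel({7: 0.5})


class TestFactors:
    def test_raw_factor_is_hits_per_gene(self):
        ft = compute_raw_factors({"6.1.1": 98_556}, {"6.1.1": 7_752})
        assert round(ft.rf["6.1.1"], 2) == 12.71
        ft = compute_raw_factors({"6.1.1": 260}, {"6.1.1": 259})
        assert round(ft.rf["6.1.1"], 2) == 1.00

    def test_zero_hits_gives_zero_factor(self):
        ft = compute_raw_factors({}, {"1.1.1": 5})
        assert ft.rf["1.1.1"] == 0.0

    def test_zero_gene_categories_reported_as_orphans(self):
        ft = compute_raw_factors({"9.9.9": 12}, {"1.1.1": 5})
        assert ft.orphans == {"9.9.9": 12}
        assert "9.9.9" not in ft.rf

    def test_normalization_reference_exactly_one(self):
        ft = compute_raw_factors({"6.1.1": 120, "1.1.1": 60}, {"6.1.1": 10, "1.1.1": 10})
        nft = normalize_factors(ft)
        assert nft.nf["6.1.1"] == 1.0
        assert nft.sd["6.1.1"] == 0.0
        assert nft.nf["1.1.1"] == pytest.approx(0.5)
        again = normalize_factors(nft)
        assert again.nf == nft.nf

    def test_zero_reference_rejected(self):
        ft = compute_raw_factors({"1.1.1": 3}, {"1.1.1": 3})
        with pytest.raises(ValueError, match="reference"):
            normalize_factors(ft)

    def test_tsv_roundtrip(self, tmp_path):
        ft = FactorTable(50, {"6.1.1": 0.6, "1.1.1": 0.3}, {"6.1.1": 1.0, "1.1.1": 0.5},
                         {"6.1.1": 0.0, "1.1.1": 0.02})
        path = tmp_path / "ft.tsv"
        ft.to_tsv(path)
        back = FactorTable.from_tsv(path)
        assert back.read_length_nt == 50
        assert back.rf == pytest.approx(ft.rf)
        assert back.nf == pytest.approx(ft.nf)
        assert back.sd == pytest.approx(ft.sd)


class TestCalibrationOnFixtures:
    def test_asymptotic_rf_equals_planted_sps_per_gene(self, small_fixture):
        ft = asymptotic_factors(small_fixture.genomes, small_fixture.dictionary)
        assert ft.rf == small_fixture.truth.asymptotic_rf

    def test_finite_read_rf_depressed_and_monotone_in_read_length(self, small_fixture):
        asym = asymptotic_factors(small_fixture.genomes, small_fixture.dictionary)
        ft50 = calibrate_pooled(small_fixture.genomes, small_fixture.dictionary, 50, 8.0, seed=0)
        ft200 = calibrate_pooled(small_fixture.genomes, small_fixture.dictionary, 200, 8.0, seed=0)
        for ec in asym.rf:
            assert ft50.rf[ec] < asym.rf[ec]
            assert ft200.rf[ec] <= asym.rf[ec] * 1.05
            assert ft50.rf[ec] < ft200.rf[ec]

    def test_nf_stable_across_read_lengths(self, small_fixture):
        ft50 = calibrate_pooled(small_fixture.genomes, small_fixture.dictionary, 50, 20.0, seed=1)
        ft200 = calibrate_pooled(small_fixture.genomes, small_fixture.dictionary, 200, 20.0, seed=1)
        for ec in ft50.nf:
            # normalized factors are approximately read-length invariant;
            # residual spread comes from per-category SP length differences
            assert ft50.nf[ec] == pytest.approx(ft200.nf[ec], rel=0.35)

    def test_superorganism_table_shape_and_reference(self, small_fixture):
        ft = train_superorganisms(
            small_fixture.genomes, small_fixture.dictionary,
            k=2, n_combinations=3, read_length_nt=50, coverage=5.0, seed=0,
        )
        assert set(ft.nf) == set(small_fixture.truth.asymptotic_rf)
        assert ft.nf["6.1.1"] == 1.0 and ft.sd["6.1.1"] == 0.0
        assert all(s >= 0 for s in ft.sd.values())

    def test_single_combination_has_zero_sd(self, small_fixture):
        ft = train_superorganisms(
            small_fixture.genomes, small_fixture.dictionary,
            k=3, n_combinations=1, read_length_nt=50, coverage=5.0, seed=0,
        )
        assert all(s == 0.0 for s in ft.sd.values())

    def test_too_many_combinations_rejected(self, small_fixture):
        with pytest.raises(ValueError):
            train_superorganisms(
                small_fixture.genomes, small_fixture.dictionary,
                k=2, n_combinations=10,
            )
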