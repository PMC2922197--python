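"""S61 selection, taxon factors and mixture prediction."""

import pytest

from spsr.match import HitTable
from spsr.sp_dictionary import ECLabel
from spsr.taxonomy import (
    AarsMultiplicity,
    TaxonFactorTable,
    load_aars_multiplicity,
    load_taxon_factors,
    percent_multiples,
    precision,
    predict_taxon_mixture,
    select_s61,
)


class TestPercentMultiples:
    @pytest.mark.parametrize(
        "ec,doublets,triplets,proteins,expected",
        [
            ("6.1.1.13", 68, 1, 172, 40.70),
            ("6.1.1.9", 0, 0, 293, 0.00),
            ("6.1.1.14", 276, 0, 825, 33.45),
        ],
    )
    def test_values(self, ec, doublets, triplets, proteins, expected):
        row = AarsMultiplicity(ECLabel.parse(ec), doublets, triplets, proteins)
        assert round(percent_multiples(row), 2) == expected

    def test_packaged_table_regression(self):
        """Recomputing % multiples from the packaged counts reproduces every
        transcribed value to 2 decimals (21 categories)."""
        import importlib.resources

        import pandas as pd

        ref = importlib.resources.files("spsr.data") / "aars_multiplicity.tsv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", dtype={"ec": str})
        assert len(df) == 21
        for r in df.itertuples():
            row = AarsMultiplicity(
                ECLabel.parse(r.ec), int(r.doublets), int(r.triplets), int(r.proteins)
            )
            assert round(percent_multiples(row), 2) == pytest.approx(r.pct_multiples)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            AarsMultiplicity(ECLabel.parse("6.1.1.1"), 10, 0, 5)

    def test_zero_proteins_rejected(self):
        with pytest.raises(ValueError):
            percent_multiples(AarsMultiplicity(ECLabel.parse("6.1.1.1"), 0, 0, 0))


class TestSelectS61:
    def test_reproduces_packaged_single_copy_set(self):
        """The <=2% rule (after 1-decimal rounding) recovers exactly the 14
        marked single-copy categories, including the 2.03% borderline one."""
        import importlib.resources

        import pandas as pd

        rows = load_aars_multiplicity()
        selected = {str(e) for e in select_s61(rows, 2.0)}
        ref = importlib.resources.files("spsr.data") / "aars_multiplicity.tsv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", dtype={"ec": str})
        marked = set(df[df.s61 == "x"].ec)
        assert selected == marked
        assert len(selected) == 14
        assert "6.1.1.16" in selected  # 2.03% rounds to 2.0
        assert "6.1.1.2" not in selected  # 2.40% stays out

    def test_zero_threshold_keeps_only_zero_multiples(self):
        selected = {str(e) for e in select_s61(load_aars_multiplicity(), 0.0)}
        assert selected == {"6.1.1.9", "6.1.1.18"}

    def test_threshold_100_keeps_all(self):
        rows = load_aars_multiplicity()
        assert len(select_s61(rows, 100.0)) == len(rows)


class TestTaxonFactors:
    def test_packaged_factors_self_consistent(self):
        """factor == hits/enzymes to 2 decimals for every packaged row."""
        table = load_taxon_factors()
        assert len(table.rows) == 25
        for r in table.rows:
            assert round(r.n_hits / r.n_enzymes, 2) == pytest.approx(r.factor)

    def test_lookup(self):
        table = load_taxon_factors()
        assert table.factor_for("Bacteria") == pytest.approx(12.71)
        assert table.factor_for("Aquificae") is None


class TestPredictTaxonMixture:
    def test_division_by_factor(self):
        hits = HitTable(counts={"Bacteria": 1271}, key="taxon")
        mixture = predict_taxon_mixture(hits, load_taxon_factors(), "kingdom")
        assert mixture.predicted_enzymes["Bacteria"] == pytest.approx(100.0, rel=1e-3)

    def test_percentages_among_called(self):
        factors = load_taxon_factors()
        hits = HitTable(
            counts={
                # chosen so hits/factor gives a 45/45/8/2 split
                "Alphaproteobacteria": round(45 * 4.37),
                "Gammaproteobacteria": round(45 * 5.74),
                "Betaproteobacteria": round(8 * 3.06),
                "Epsilonproteobacteria": round(2 * 1.93),
            },
            key="taxon",
        )
        mixture = predict_taxon_mixture(hits, factors, "class")
        pct = mixture.percent_among_called
        assert pct["Alphaproteobacteria"] == pytest.approx(45, abs=1)
        assert pct["Gammaproteobacteria"] == pytest.approx(45, abs=1)
        assert pct["Betaproteobacteria"] == pytest.approx(8, abs=1)
        assert pct["Epsilonproteobacteria"] == pytest.approx(2, abs=1)

    def test_below_threshold_goes_to_no_call(self):
        hits = HitTable(counts={"Thermotogae": 0}, key="taxon")
        hits.counts["Thermotogae"] = 0  # 0 hits -> predicted 0 < 1
        mixture = predict_taxon_mixture(hits, load_taxon_factors(), "phylum")
        assert "Thermotogae" in mixture.no_call
        assert mixture.predicted_enzymes == {}

    def test_taxon_without_factor_is_no_prediction(self):
        hits = HitTable(counts={"Aquificae": 10}, key="taxon")
        mixture = predict_taxon_mixture(hits, load_taxon_factors(), "phylum")
        assert "Aquificae" in mixture.no_prediction

    def test_requires_taxon_keyed_table(self):
        with pytest.raises(ValueError):
            predict_taxon_mixture(HitTable(key="ec3"), load_taxon_factors(), "phylum")


class TestPrecision:
    def test_definition(self):
        assert precision(96, 4) == pytest.approx(96.0)
        assert precision(1, 0) == pytest.approx(100.0)

    def test_undefined_on_empty(self):
        with pytest.raises(ValueError):
            precision(0, 0)

    def test_fixture_genome_classified_at_full_precision(self, taxon_fixture):
        """With no cross-taxon TSPs planted, a single-phylum genome yields
        TP-only hits: precision 100%."""
        from spsr.match import build_matcher, scan_reads
        from spsr.sixframe import ShortRead

        matcher = build_matcher(taxon_fixture.dictionary)
        g = taxon_fixture.genomes[0]  # Proteobacteria fixture genome
        _, table = scan_reads([ShortRead(g.genome_id, g.sequence)], matcher, key="taxon")
        tp = table.counts.get("Proteobacteria", 0)
        fp = sum(v for k, v in table.counts.items() if k != "Proteobacteria")
        assert tp > 0
        assert precision(tp, fp) == 100.0
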