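"""End-to-end recovery experiments on synthetic study sets.

These protocols exercise the whole pipeline — fixture construction, read
simulation, six-frame matching, factor training, spectrum and mixture
prediction — against ground truth recorded at fixture-construction time.
They are used both by the test suite and by the reproduction script.

Problem sizes are deliberately desk-scale: five ~10-kb genomes at 5x
coverage give a few hundred to a few thousand hits per category, enough for
the percent-level comparisons made here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibrate import (
    EfficiencyModel,
    FactorTable,
    asymptotic_factors,
    compute_raw_factors,
    normalize_factors,
    simulate_reads,
    total_efficiency,
    train_superorganisms,
)
from .fixtures import Fixture, FixtureSpec, build_fixture
from .match import HitTable, build_matcher, flag_anomalies, scan_reads
from .sixframe import ShortRead
from .spectrum import chi_square_fit, predict_spectrum
from .taxonomy import TaxonFactorRow, TaxonFactorTable, predict_taxon_mixture

__all__ = [
    "recovery_fixture_spec",
    "RecoveryResult",
    "parameter_recovery",
    "TaxonMixtureResult",
    "taxon_mixture_recovery",
    "anomaly_detection_check",
]


def recovery_fixture_spec(seed: int) -> FixtureSpec:
    """Five heterogeneous toy genomes for calibration-recovery experiments.

    Gene counts and SP densities vary across genomes (real organisms differ
    in both enzyme repertoire and marker-peptide content); the reference
    aaRS-like category 6.1.1 is kept homogeneous and single-density, mirroring
    its role as the calibrating device.
    """
    return FixtureSpec(
        n_genomes=5,
        genome_length_nt=36_000,
        genes_per_ec={"1.1.1.1": 18, "2.7.7.7": 15, "3.6.1.3": 12, "6.1.1.1": 12},
        genes_per_genome={
            0: {"1.1.1.1": 18, "2.7.7.7": 15, "3.6.1.3": 12, "6.1.1.1": 12},
            1: {"1.1.1.1": 24, "2.7.7.7": 9, "3.6.1.3": 18, "6.1.1.1": 12},
            2: {"1.1.1.1": 12, "2.7.7.7": 21, "3.6.1.3": 12, "6.1.1.1": 12},
            3: {"1.1.1.1": 18, "2.7.7.7": 15, "3.6.1.3": 18, "6.1.1.1": 12},
            4: {"1.1.1.1": 24, "2.7.7.7": 15, "3.6.1.3": 12, "6.1.1.1": 12},
        },
        sp_repeats_per_genome={
            0: {"1.1.1.1": 1, "2.7.7.7": 2, "3.6.1.3": 1},
            1: {"1.1.1.1": 2, "2.7.7.7": 1, "3.6.1.3": 1},
            2: {"1.1.1.1": 1, "2.7.7.7": 1, "3.6.1.3": 2},
            3: {"1.1.1.1": 2, "2.7.7.7": 2, "3.6.1.3": 1},
            4: {"1.1.1.1": 1, "2.7.7.7": 2, "3.6.1.3": 2},
        },
        sps_per_gene=2,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    fixture: Fixture
    factor_table: FactorTable
    #: max relative error of the full-genome (asymptotic) RF vs planted truth
    asymptotic_max_rel_error: float
    #: read length -> (measured finite/asymptotic hit ratio, efficiency model value)
    efficiency: dict[int, tuple[float, float]]
    #: EC -> (predicted per unit coverage, truth, propagated sd) on a pooled
    #: 3-genome metagenome
    pooled_prediction: dict[str, tuple[float, float, float]]
    chi2_pooled: float
    chi2_single_mean: float


def _occurrence_weighted_model(fixture: Fixture) -> EfficiencyModel:
    """SP length distribution weighted by planted occurrences."""
    length_of = {p.sequence: len(p.sequence) for p in fixture.dictionary}
    weights: dict[int, float] = {}
    for counts in fixture.truth.sp_counts.values():
        for sp, n in counts.items():
            L = length_of[sp]
            weights[L] = weights.get(L, 0.0) + n
    total = sum(weights.values())
    return EfficiencyModel({L: w / total for L, w in weights.items()})


def parameter_recovery(
    seed: int,
    read_lengths: tuple[int, ...] = (50, 100, 200),
    coverage: float = 5.0,
) -> RecoveryResult:
    """Full calibration-and-recovery experiment on the five-genome fixture.

    * asymptotic factors from un-fragmented genomes vs planted truth (exact);
    * finite-read/asymptotic hit ratio vs the geometric efficiency model at
      each read length;
    * factor training on the 10 3-genome super-organisms at 50 nt, then
      absolute predictions for a pooled 3-genome metagenome vs known gene
      counts, with the propagated standard deviation
      sd_rel * truth * sqrt(1 + 1/n_combinations);
    * chi-square per degree of freedom for the pooled metagenome vs the mean
      over single genomes (metagenomic averaging smooths organism
      idiosyncrasies, so the single-genome statistic should be larger).
    """
    rng = np.random.default_rng(seed)
    fixture = build_fixture(recovery_fixture_spec(seed))
    genomes, dictionary, truth = fixture.genomes, fixture.dictionary, fixture.truth
    matcher = build_matcher(dictionary)

    asym = asymptotic_factors(genomes, dictionary)
    asym_err = max(
        abs(asym.rf[ec] - truth.asymptotic_rf[ec]) / truth.asymptotic_rf[ec]
        for ec in truth.asymptotic_rf
    )
    total_asym_hits = sum(
        n for counts in truth.sp_counts.values() for n in counts.values()
    )

    model = _occurrence_weighted_model(fixture)
    efficiency: dict[int, tuple[float, float]] = {}
    for rl in read_lengths:
        finite_hits = 0
        for g in genomes:
            reads = simulate_reads(g.sequence, rl, coverage, rng)
            _, table = scan_reads(reads, matcher, collect_hits=False)
            finite_hits += table.total_hits
        measured = finite_hits / (coverage * total_asym_hits)
        efficiency[rl] = (measured, total_efficiency(model, rl))

    n_combinations = 10
    ft = train_superorganisms(
        genomes, dictionary, k=3, n_combinations=n_combinations,
        read_length_nt=50, coverage=coverage, seed=int(rng.integers(2**31)),
    )

    pool = genomes[:3]
    pooled_counts: dict[str, int] = {}
    for g in pool:
        reads = simulate_reads(g.sequence, 50, coverage, rng)
        _, table = scan_reads(reads, matcher, collect_hits=False)
        for k_, v in table.counts.items():
            pooled_counts[k_] = pooled_counts.get(k_, 0) + v
    pooled_table = HitTable(counts=pooled_counts, mean_read_length=50.0)
    spec_pooled = predict_spectrum(pooled_table, ft)
    pooled_truth = {}
    for g in pool:
        for ec, n in g.enzyme_counts.items():
            pooled_truth[ec] = pooled_truth.get(ec, 0) + n
    sd_infl = math.sqrt(1 + 1 / n_combinations)
    pooled_prediction = {}
    sd_abs = {}
    for ec, known in pooled_truth.items():
        sd_rel = ft.sd[ec] / ft.nf[ec] if ft.nf.get(ec) else 0.0
        sd_here = sd_rel * known * sd_infl
        if ec == ft.reference:
            # reference sd is 0 by construction; use the Poisson counting
            # error of calibration + test hits instead
            sd_here = known * math.sqrt(2.0 / max(pooled_counts.get(ec, 1), 1))
        pooled_prediction[ec] = (spec_pooled.predicted[ec] / coverage, known, sd_here)
        sd_abs[ec] = sd_here
    fit_pooled = chi_square_fit(
        {ec: v / coverage for ec, v in spec_pooled.predicted.items()},
        {ec: float(v) for ec, v in pooled_truth.items()},
        sd_abs,
    )

    single_chi2 = []
    for g in genomes:
        reads = simulate_reads(g.sequence, 50, coverage, rng)
        _, table = scan_reads(reads, matcher, collect_hits=False)
        spec_single = predict_spectrum(
            HitTable(counts=table.counts, mean_read_length=50.0), ft
        )
        known = {ec: float(n) for ec, n in g.enzyme_counts.items()}
        sd_single = {}
        for ec, kn in known.items():
            sd_rel = ft.sd[ec] / ft.nf[ec] if ft.nf.get(ec) else 0.0
            sd_single[ec] = sd_rel * kn * sd_infl
            if ec == ft.reference:
                sd_single[ec] = kn * math.sqrt(2.0 / max(table.counts.get(ec, 1), 1))
        fit = chi_square_fit(
            {ec: v / coverage for ec, v in spec_single.predicted.items()},
            known, sd_single,
        )
        single_chi2.append(fit.chi2_per_dof)

    return RecoveryResult(
        fixture, ft, asym_err, efficiency, pooled_prediction,
        fit_pooled.chi2_per_dof, float(np.mean(single_chi2)),
    )


@dataclass
class TaxonMixtureResult:
    ratios: list[float]
    mean_ratio: float
    target_ratio: float
    no_call_taxa: set[str] = field(default_factory=set)


def taxon_mixture_recovery(
    seed: int,
    n_seeds: int = 5,
    target_ratio: float = 3.0,
    read_length_nt: int = 100,
) -> TaxonMixtureResult:
    """Mix reads of two fixture phyla at a known cell ratio and recover it.

    One Proteobacteria and one Firmicutes genome carry phylum-specific TSP
    sets.  Per replicate: taxon factors are calibrated from deep simulated
    reads of each genome (hits per enzyme per unit coverage), then a mixed
    read set at coverages ``target_ratio * 3 : 3`` is classified and the
    predicted-enzyme ratio compared with the target.

    Also runs a single-TSP-hit read set through the classifier to exercise
    the no-call rule: one hit divided by a factor above 1 predicts less than
    one enzyme, which must be refused rather than assigned.
    """
    spec = FixtureSpec(
        n_genomes=2,
        genome_length_nt=14_000,
        genes_per_ec={"6.1.1.3": 12, "6.1.1.4": 12},
        sps_per_gene=2,
        taxon_assignment={0: "Proteobacteria", 1: "Firmicutes"},
        seed=seed,
    )
    fixture = build_fixture(spec)
    matcher = build_matcher(fixture.dictionary)
    genome_of = {spec.taxon_assignment[i]: fixture.genomes[i] for i in (0, 1)}
    enzymes = fixture.truth.taxon_enzymes

    rng = np.random.default_rng(seed + 1)
    ratios = []
    no_call_taxa: set[str] = set()
    for _ in range(n_seeds):
        # calibrate per-taxon factors at high coverage
        rows = []
        cal_cov = 40.0
        for taxon, genome in genome_of.items():
            reads = simulate_reads(genome.sequence, read_length_nt, cal_cov, rng)
            _, table = scan_reads(reads, matcher, key="taxon", collect_hits=False)
            hits = table.counts.get(taxon, 0)
            rows.append(
                TaxonFactorRow("Bacteria", taxon, enzymes[taxon], 0, hits,
                               hits / (cal_cov * enzymes[taxon]))
            )
        factors = TaxonFactorTable(rows)

        base_cov = 5.0
        mixed: dict[str, int] = {}
        for taxon, cov in (("Proteobacteria", target_ratio * base_cov),
                           ("Firmicutes", base_cov)):
            reads = simulate_reads(genome_of[taxon].sequence, read_length_nt, cov, rng)
            _, table = scan_reads(reads, matcher, key="taxon", collect_hits=False)
            for k_, v in table.counts.items():
                mixed[k_] = mixed.get(k_, 0) + v
        mixture = predict_taxon_mixture(
            HitTable(counts=mixed, key="taxon"), factors, "phylum"
        )
        pred = mixture.predicted_enzymes
        ratios.append(pred["Proteobacteria"] / pred["Firmicutes"])

        # shallow data: a single TSP hit predicts < 1 enzyme (the per-enzyme
        # factor exceeds 1) and must be refused, not reported
        from .fixtures import _encode

        sp = next(
            p.sequence for p in fixture.dictionary if p.taxon and p.taxon.name == "Firmicutes"
        )
        shallow_read = ShortRead("shallow", _encode(sp, rng) + "ACGACG")
        _, shallow = scan_reads([shallow_read], matcher, key="taxon")
        assert shallow.counts == {"Firmicutes": 1}
        shallow_mix = predict_taxon_mixture(
            HitTable(counts=dict(shallow.counts), key="taxon"), factors, "phylum"
        )
        no_call_taxa |= shallow_mix.no_call
        assert "Firmicutes" not in shallow_mix.predicted_enzymes

    return TaxonMixtureResult(
        ratios, float(np.mean(ratios)), target_ratio, no_call_taxa
    )


def anomaly_detection_check(seed: int) -> tuple[list, list]:
    """Scan a contaminated and a uniform read set; return both anomaly lists.

    The contaminated set plants one read pair of overlapping same-EC SPs
    hundreds of times (a single over-amplified fragment); the uniform set
    spreads comparable counts over many categories and peptides.
    """
    from .fixtures import _encode, make_sp
    from .sp_dictionary import ECLabel, SPDictionary, SpecificPeptide

    rng = np.random.default_rng(seed)
    # overlapping pair: the second SP starts inside the first
    a = make_sp(9, rng)
    b = a[2:] + make_sp(7, rng, forbidden=[a])
    other_ecs = [f"1.1.{i}" for i in range(1, 7)]
    peptides = {SpecificPeptide(a, ECLabel.parse("5.4.99.2")),
                SpecificPeptide(b, ECLabel.parse("5.4.99.2"))}
    other_sps: dict[str, list[str]] = {}
    forbidden = [a, b]
    for ec in other_ecs:
        other_sps[ec] = [make_sp(8, rng, forbidden=forbidden) for _ in range(4)]
        forbidden += other_sps[ec]
    for ec, sps in other_sps.items():
        peptides |= {SpecificPeptide(s, ECLabel.parse(ec)) for s in sps}
    dictionary = SPDictionary(frozenset(peptides))
    matcher = build_matcher(dictionary)

    carrier = _encode(a + b[len(a) - 2:], rng)  # one read carrying both SPs
    contaminated = [ShortRead(f"c{i}", carrier) for i in range(230)]
    for i in range(40):
        ec = other_ecs[i % len(other_ecs)]
        sp = other_sps[ec][i % 4]
        contaminated.append(ShortRead(f"b{i}", _encode(sp, rng) + "ACG"))
    _, table_bad = scan_reads(contaminated, matcher, collect_hits=False)

    uniform = []
    for i in range(240):
        ec = other_ecs[i % len(other_ecs)]
        sp = other_sps[ec][i % 4]
        uniform.append(ShortRead(f"u{i}", _encode(sp, rng) + "ACG"))
    _, table_uniform = scan_reads(uniform, matcher, collect_hits=False)

    return flag_anomalies(table_bad), flag_anomalies(table_uniform)
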