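"""Calibration of raw and normalized factors from annotated genomes.

The raw factor RF(EC) = (number of SP hits) / (number of annotated enzyme
genes) converts hit counts into predicted gene numbers.  Evaluated on a full
genome it equals the average number of SP hits per enzyme of that category
(the asymptotic factor).  On finite reads of length k it is depressed,
because an SP of L amino acids must fit entirely inside one read: with
W = floor(k/3) available residues the relative detection efficiency is
(W - L + 1)/W, which for k = 50 (W = 16) is (17 - L)/16.

Raw factors computed from simulated reads are reported per unit coverage, so
that they are directly comparable with the asymptotic factor and so that
predictions on a metagenome of unknown depth return gene copies x coverage
("coverage content").

Normalized factors NF(EC) = RF(EC)/RF(6.1.1) divide out the geometry shared
by all categories; they are approximately read-length invariant, which is
what makes them usable on metagenomes of varying read length.  The reference
6.1.1 (aminoacyl-tRNA synthetases) has the largest factor and is essentially
single-copy per bacterial genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .match import HitTable, Matcher, build_matcher, scan_reads
from .sixframe import ShortRead
from .sp_dictionary import ECLabel, SPDictionary

__all__ = [
    "Gene",
    "AnnotatedGenome",
    "FactorTable",
    "EfficiencyModel",
    "simulate_reads",
    "relative_efficiency",
    "total_efficiency",
    "compute_raw_factors",
    "normalize_factors",
    "calibrate_pooled",
    "asymptotic_factors",
    "train_superorganisms",
    "load_annotation",
    "save_annotation",
]

log = logging.getLogger(__name__)

REFERENCE_EC = "6.1.1"


@dataclass(frozen=True)
class Gene:
    """An annotated gene: 1-based inclusive coordinates on the genome."""

    gene_id: str
    start: int
    end: int
    strand: str
    ec_labels: tuple[ECLabel, ...]


@dataclass
class AnnotatedGenome:
    genome_id: str
    sequence: str
    genes: list[Gene]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def enzyme_counts(self) -> dict[str, int]:
        """Number of annotated enzyme genes per EC level-3 category.

        A gene with several EC labels counts once in each of their level-3
        categories.
        """
        counts: dict[str, int] = {}
        for gene in self.genes:
            for cat in {str(ec.level3()) for ec in gene.ec_labels}:
                counts[cat] = counts.get(cat, 0) + 1
        return counts


def _merge_counts(dicts: Iterable[dict[str, int]]) -> dict[str, int]:
    out: dict[str, int] = {}
    for d in dicts:
        for k, v in d.items():
            out[k] = out.get(k, 0) + v
    return out


@dataclass
class FactorTable:
    """Per-EC raw factors, normalized factors and their standard deviations.

    ``read_length_nt`` is ``None`` for asymptotic (full-genome) factors.
    ``orphans`` holds categories that had hits but zero annotated genes;
    they cannot be divided and are reported, not dropped.
    """

    read_length_nt: int | None
    rf: dict[str, float]
    nf: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    reference: str = REFERENCE_EC
    orphans: dict[str, int] = field(default_factory=dict)
    table_id: str = ""

    def categories(self) -> list[str]:
        return sorted(self.rf or self.nf)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ec\tread_length\trf\tnf\tsd\n")
            rl = "" if self.read_length_nt is None else self.read_length_nt
            for ec in self.categories():
                rf = self.rf.get(ec, "")
                nf = self.nf.get(ec, "")
                sd = self.sd.get(ec, "")
                fh.write(f"{ec}\t{rl}\t{rf}\t{nf}\t{sd}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, reference: str = REFERENCE_EC) -> "FactorTable":
        df = pd.read_csv(path, sep="\t", dtype={"ec": str})
        rls = df["read_length"].dropna().unique()
        read_length = int(rls[0]) if len(rls) else None
        rf = {
            row.ec: float(row.rf)
            for row in df.itertuples()
            if not pd.isna(row.rf)
        }
        nf = {
            row.ec: float(row.nf)
            for row in df.itertuples()
            if not pd.isna(row.nf)
        }
        sd = {
            row.ec: float(row.sd)
            for row in df.itertuples()
            if not pd.isna(row.sd)
        }
        return cls(read_length, rf, nf, sd, reference=reference, table_id=str(path))


@dataclass
class EfficiencyModel:
    """Distribution of SP lengths, used to predict finite-read efficiency."""

    sp_length_distribution: dict[int, float]

    def __post_init__(self) -> None:
        dist = self.sp_length_distribution
        if not dist or any(L < 7 for L in dist):
            raise ValueError("SP length distribution needs support on L >= 7")
        total = sum(dist.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"distribution sums to {total}, not 1")

    @classmethod
    def from_dictionary(cls, d: SPDictionary) -> "EfficiencyModel":
        lengths = [len(p) for p in d]
        n = len(lengths)
        dist: dict[int, float] = {}
        for L in lengths:
            dist[L] = dist.get(L, 0.0) + 1.0 / n
        return cls(dist)


def simulate_reads(
    genome: str,
    read_length_nt: int,
    coverage: float,
    seed: int | np.random.Generator,
) -> list[ShortRead]:
    """Fragment a genome into uniformly placed reads at the given coverage.

    Number of reads is ceil(coverage * genome_length / read_length); start
    positions are independent uniform draws on the forward strand (the
    six-frame search restores strand symmetry).  Reproducible under a fixed
    seed.
    """
    genome_length = len(genome)
    if read_length_nt > genome_length:
        raise ValueError(
            f"read length {read_length_nt} exceeds genome length {genome_length}"
        )
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    n_reads = math.ceil(coverage * genome_length / read_length_nt)
    if n_reads < 1:
        log.warning("requested coverage yields < 1 read; emitting 1")
        n_reads = 1
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = rng.integers(0, genome_length - read_length_nt + 1, size=n_reads)
    return [
        ShortRead(f"sim_{i}", genome[s : s + read_length_nt])
        for i, s in enumerate(starts)
    ]


def relative_efficiency(L: int, read_length_nt: int) -> float:
    """Probability-proportional efficiency of seeing an L-residue SP in a read.

    With W = floor(read_length/3) residues per frame, an L-mer fits in
    W - L + 1 positions out of W: efficiency max(0, W - L + 1)/W.  For 50-nt
    reads this is the (17 - L)/16 rule; SPs longer than 16 residues are
    invisible at that read length.
    """
    if L < 1:
        raise ValueError("SP length must be >= 1")
    if read_length_nt < 3:
        raise ValueError("read length must be >= 3 nt")
    W = read_length_nt // 3
    return max(0, W - L + 1) / W


def total_efficiency(model: EfficiencyModel, read_length_nt: int) -> float:
    """Expected efficiency over the SP length distribution; -> 1 as reads grow."""
    return sum(
        p * relative_efficiency(L, read_length_nt)
        for L, p in model.sp_length_distribution.items()
    )


def compute_raw_factors(
    hits: HitTable | dict[str, int],
    enzyme_counts: dict[str, int],
    read_length_nt: int | None = None,
    coverage: float = 1.0,
) -> FactorTable:
    """RF(EC) = hits / (coverage * enzyme genes), per category.

    Categories with hits but no annotated genes go into ``orphans``.
    Categories with genes but no hits get RF = 0.
    """
    counts = hits.counts if isinstance(hits, HitTable) else hits
    rf: dict[str, float] = {}
    orphans: dict[str, int] = {}
    for cat, n_hits in counts.items():
        genes = enzyme_counts.get(cat, 0)
        if genes > 0:
            rf[cat] = n_hits / (coverage * genes)
        else:
            orphans[cat] = n_hits
    for cat, genes in enzyme_counts.items():
        if genes > 0:
            rf.setdefault(cat, 0.0)
    return FactorTable(read_length_nt, rf, orphans=orphans)


def normalize_factors(ft: FactorTable, reference: str = REFERENCE_EC) -> FactorTable:
    """NF(EC) = RF(EC)/RF(reference); NF(reference) is exactly 1, SD 0."""
    ref_rf = ft.rf.get(reference, 0.0)
    if ref_rf <= 0:
        raise ValueError(f"reference category {reference!r} has zero raw factor")
    nf = {cat: rf / ref_rf for cat, rf in ft.rf.items()}
    nf[reference] = 1.0
    sd = dict(ft.sd)
    sd[reference] = 0.0
    return replace(ft, nf=nf, sd=sd, reference=reference)


def _scan_simulated(
    genomes: Sequence[AnnotatedGenome],
    matcher: Matcher,
    read_length_nt: int,
    coverage: float,
    rng: np.random.Generator,
) -> HitTable:
    pooled: HitTable | None = None
    for g in genomes:
        reads = simulate_reads(g.sequence, read_length_nt, coverage, rng)
        _, table = scan_reads(reads, matcher, collect_hits=False)
        if pooled is None:
            pooled = table
        else:
            pooled.counts = _merge_counts([pooled.counts, table.counts])
            pooled.n_reads += table.n_reads
    assert pooled is not None
    return pooled


def calibrate_pooled(
    genomes: Sequence[AnnotatedGenome],
    dictionary: SPDictionary,
    read_length_nt: int,
    coverage: float,
    seed: int | np.random.Generator,
) -> FactorTable:
    """Simulate reads over pooled genomes and derive normalized factors."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    matcher = build_matcher(dictionary)
    table = _scan_simulated(genomes, matcher, read_length_nt, coverage, rng)
    enzyme_counts = _merge_counts(g.enzyme_counts for g in genomes)
    ft = compute_raw_factors(table, enzyme_counts, read_length_nt, coverage=coverage)
    return normalize_factors(ft)


def asymptotic_factors(
    genomes: Sequence[AnnotatedGenome],
    dictionary: SPDictionary,
) -> FactorTable:
    """Factors from the un-fragmented genomes: average SP hits per enzyme."""
    matcher = build_matcher(dictionary)
    tables = []
    for g in genomes:
        _, table = scan_reads(
            [ShortRead(g.genome_id, g.sequence)], matcher, collect_hits=False
        )
        tables.append(table.counts)
    counts = _merge_counts(tables)
    enzyme_counts = _merge_counts(g.enzyme_counts for g in genomes)
    ft = compute_raw_factors(counts, enzyme_counts, read_length_nt=None)
    return normalize_factors(ft)


def train_superorganisms(
    genomes: Sequence[AnnotatedGenome],
    dictionary: SPDictionary,
    k: int = 7,
    n_combinations: int = 15,
    read_length_nt: int = 50,
    coverage: float = 5.0,
    seed: int = 0,
) -> FactorTable:
    """Train factors on artificial metagenomes ("super-organisms").

    Samples ``n_combinations`` distinct k-subsets of the genomes (uniformly,
    without replacement, seeded), pools each subset into one artificial
    metagenome, simulates reads and derives normalized factors; reports the
    per-EC mean NF and sample SD (ddof=1) across combinations.  Categories
    absent from a combination's annotation are skipped for that combination.
    """
    n = len(genomes)
    if k > n:
        raise ValueError(f"k={k} exceeds number of genomes {n}")
    all_combos = list(combinations(range(n), k))
    if n_combinations > len(all_combos):
        raise ValueError(
            f"requested {n_combinations} combinations but only {len(all_combos)} exist"
        )
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(all_combos), size=n_combinations, replace=False)
    per_ec_nf: dict[str, list[float]] = {}
    per_ec_rf: dict[str, list[float]] = {}
    for ci in chosen_idx:
        subset = [genomes[i] for i in all_combos[ci]]
        ft = calibrate_pooled(subset, dictionary, read_length_nt, coverage, rng)
        for cat, val in ft.nf.items():
            per_ec_nf.setdefault(cat, []).append(val)
        for cat, val in ft.rf.items():
            per_ec_rf.setdefault(cat, []).append(val)
    nf = {cat: float(np.mean(v)) for cat, v in per_ec_nf.items()}
    rf = {cat: float(np.mean(v)) for cat, v in per_ec_rf.items()}
    sd = {
        cat: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        for cat, v in per_ec_nf.items()
    }
    nf[REFERENCE_EC] = 1.0
    sd[REFERENCE_EC] = 0.0
    ft = FactorTable(
        read_length_nt, rf, nf, sd,
        table_id=f"superorganisms(k={k},n={n_combinations},l={read_length_nt})",
    )
    return ft


def load_annotation(path: str | Path) -> list[Gene]:
    """Read a gene annotation TSV: gene_id, start, end, strand, ec.

    Coordinates are 1-based inclusive; ``ec`` may hold several labels
    separated by commas.
    """
    genes: list[Gene] = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "start", "end", "strand", "ec"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation column(s) {sorted(missing)}")
    for row in df.itertuples():
        labels = tuple(ECLabel.parse(t) for t in str(row.ec).split(",") if t.strip())
        genes.append(Gene(row.gene_id, int(row.start), int(row.end), row.strand, labels))
    return genes


def save_annotation(genes: Iterable[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tstrand\tec\n")
        for g in genes:
            ecs = ",".join(str(e) for e in g.ec_labels)
            fh.write(f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{ecs}\n")
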