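"""Synthetic genomes, SP dictionaries and read sets with known ground truth.

Every pipeline stage — translation, matching, calibration, spectrum
prediction, taxonomic mixtures — is testable against fixtures whose expected
numbers are fixed at construction time:

* each planted gene encodes all of its EC category's SPs exactly once, via
  randomly chosen synonymous codons, so the asymptotic raw factor of a
  category equals ``sps_per_gene`` by construction;
* roughly half the genes are planted on the reverse strand (seeded coin
  flip), exercising all six frames;
* the assembled genome is re-scanned in six frames and rejected (re-rolled)
  unless every SP occurs exactly its planted number of times, so background
  sequence is guaranteed free of accidental hits.

Synonymous-codon randomization matters: it guarantees that matches arise
from translation, not from nucleotide-level repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .calibrate import AnnotatedGenome, Gene, save_annotation
from .match import build_matcher, scan_reads
from .sixframe import ShortRead, reverse_complement
from .sp_dictionary import (
    ECLabel,
    SPDictionary,
    SpecificPeptide,
    TaxonLabel,
    save_dictionary,
)

__all__ = ["FixtureSpec", "FixtureTruth", "Fixture", "make_sp", "build_fixture", "write_fixture"]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: amino acid -> synonymous codons, standard genetic code
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _STANDARD.forward_table.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _codons in _AA_TO_CODONS.values():
    _codons.sort()

_AA_ALPHABET = sorted(_AA_TO_CODONS)  # the 20 standard amino acids


@dataclass
class FixtureSpec:
    """Recipe for a synthetic study set.

    ``genes_per_ec`` gives genes planted per genome per EC label;
    ``taxon_assignment`` (genome index -> registered taxon name) switches the
    fixture into TSP mode: each taxon group gets its own SP set per EC,
    labelled with that taxon.
    """

    n_genomes: int = 1
    genome_length_nt: int = 10_000
    genes_per_ec: dict[str, int] = field(default_factory=lambda: {"6.1.1.1": 2})
    sps_per_gene: int = 2
    sp_lengths: tuple[int, ...] = (7, 8, 9, 10, 11, 12)
    taxon_assignment: dict[int, str] | None = None
    #: optional per-genome overrides of genes_per_ec (genome index -> counts),
    #: for heterogeneous communities
    genes_per_genome: dict[int, dict[str, int]] | None = None
    #: optional per-genome SP-density multipliers (genome index -> EC -> r):
    #: each gene of that EC encodes its SP set r times, emulating organisms
    #: whose enzymes carry more or fewer marker peptides than average
    sp_repeats_per_genome: dict[int, dict[str, int]] | None = None
    seed: int = 0

    def genes_for(self, genome_index: int) -> dict[str, int]:
        if self.genes_per_genome and genome_index in self.genes_per_genome:
            return self.genes_per_genome[genome_index]
        return self.genes_per_ec

    def repeats_for(self, genome_index: int, ec_text: str) -> int:
        if self.sp_repeats_per_genome and genome_index in self.sp_repeats_per_genome:
            return self.sp_repeats_per_genome[genome_index].get(ec_text, 1)
        return 1

    def all_ecs(self) -> list[str]:
        ecs = set(self.genes_per_ec)
        for d in (self.genes_per_genome or {}).values():
            ecs |= set(d)
        return sorted(ecs)


@dataclass
class FixtureTruth:
    """Expected values recorded at construction time (ground-truth closure)."""

    enzyme_counts: dict[str, dict[str, int]]  # genome_id -> EC3 -> genes
    pooled_enzyme_counts: dict[str, int]
    asymptotic_rf: dict[str, float]  # EC3 -> sps_per_gene
    taxon_enzymes: dict[str, int]  # taxon name -> pooled gene count
    sp_counts: dict[str, dict[str, int]]  # genome_id -> SP sequence -> occurrences


@dataclass
class Fixture:
    genomes: list[AnnotatedGenome]
    dictionary: SPDictionary
    truth: FixtureTruth


def make_sp(length: int, rng: np.random.Generator, forbidden: list[str] | None = None) -> str:
    """A random peptide over the 20-letter alphabet, absent from ``forbidden`` texts.

    Deterministic for a given rng state.  Re-rolls (bounded) until the
    peptide neither occurs in, nor contains/is contained by, any forbidden
    string.
    """
    if length < 7:
        raise ValueError("SP length must be >= 7")
    forbidden = forbidden or []
    for _ in range(1000):
        seq = "".join(rng.choice(_AA_ALPHABET, size=length))
        clash = any(seq in t or t in seq for t in forbidden)
        if not clash:
            return seq
    raise RuntimeError("could not generate a non-clashing SP")


def _encode(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniformly random synonymous codons."""
    return "".join(rng.choice(_AA_TO_CODONS[aa]) for aa in protein)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(("A", "C", "G", "T"), size=n))


def _random_aa(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA_ALPHABET, size=n))


def _build_genome(
    genome_id: str,
    spec: FixtureSpec,
    genes_per_ec: dict[str, int],
    repeats: dict[str, int],
    sp_sets: dict[str, list[str]],  # EC label text -> SP sequences for this genome
    rng: np.random.Generator,
) -> tuple[AnnotatedGenome, dict[str, int]]:
    """Assemble one genome; returns it plus expected per-SP occurrence counts."""
    gene_proteins: list[tuple[str, str]] = []  # (ec_text, protein)
    for ec_text, n_genes in genes_per_ec.items():
        sps = sp_sets[ec_text] * repeats.get(ec_text, 1)
        for _ in range(n_genes):
            parts = [_random_aa(3, rng)]
            for i, sp in enumerate(sps):
                if i:
                    parts.append(_random_aa(2, rng))
                parts.append(sp)
            parts.append(_random_aa(3, rng))
            gene_proteins.append((ec_text, "".join(parts)))
    total_gene_nt = sum(3 * len(p) for _, p in gene_proteins)
    n_genes = len(gene_proteins)
    background_nt = spec.genome_length_nt - total_gene_nt
    if background_nt < 10 * (n_genes + 1):
        raise ValueError(
            f"genome length {spec.genome_length_nt} cannot pack {n_genes} genes "
            f"({total_gene_nt} nt) with background"
        )
    # split background into n_genes + 1 gaps
    cuts = np.sort(rng.integers(0, background_nt + 1, size=n_genes))
    gaps = np.diff(np.concatenate(([0], cuts, [background_nt])))
    order = rng.permutation(n_genes)
    chunks: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for gi, gap in zip(order, gaps[:-1]):
        chunks.append(_random_nt(int(gap), rng))
        pos += int(gap)
        ec_text, protein = gene_proteins[gi]
        nt = _encode(protein, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            nt = reverse_complement(nt)
        start = pos + 1  # 1-based inclusive
        end = pos + len(nt)
        genes.append(
            Gene(f"{genome_id}_g{len(genes)}", start, end, strand, (ECLabel.parse(ec_text),))
        )
        chunks.append(nt)
        pos = end
    chunks.append(_random_nt(int(gaps[-1]), rng))
    sequence = "".join(chunks)
    assert len(sequence) == spec.genome_length_nt
    expected: dict[str, int] = {}
    for ec_text, n in genes_per_ec.items():
        if n > 0:
            for sp in sp_sets[ec_text]:
                expected[sp] = expected.get(sp, 0) + n * repeats.get(ec_text, 1)
    return AnnotatedGenome(genome_id, sequence, genes), expected


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Build genomes + dictionary + truth tables from a :class:`FixtureSpec`.

    Deterministic under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    groups: dict[str | None, list[int]] = {}
    if spec.taxon_assignment:
        for gi in range(spec.n_genomes):
            groups.setdefault(spec.taxon_assignment.get(gi), []).append(gi)
    else:
        groups[None] = list(range(spec.n_genomes))

    # one SP set per (taxon group, EC); shared by all genomes of the group
    all_sps: list[str] = []
    peptides: set[SpecificPeptide] = set()
    group_sp_sets: dict[str | None, dict[str, list[str]]] = {}
    for taxon in groups:
        sets: dict[str, list[str]] = {}
        label = TaxonLabel.from_name(taxon) if taxon else None
        for ec_text in spec.all_ecs():
            sps = []
            for _ in range(spec.sps_per_gene):
                L = int(rng.choice(spec.sp_lengths))
                sp = make_sp(L, rng, forbidden=all_sps)
                sps.append(sp)
                all_sps.append(sp)
                peptides.add(SpecificPeptide(sp, ECLabel.parse(ec_text), label))
            sets[ec_text] = sps
        group_sp_sets[taxon] = sets
    dictionary = SPDictionary(frozenset(peptides), provenance=f"fixture(seed={spec.seed})")
    matcher = build_matcher(dictionary)

    genomes: list[AnnotatedGenome] = []
    sp_counts: dict[str, dict[str, int]] = {}
    for taxon, members in groups.items():
        for gi in members:
            genome_id = f"fx{gi}"
            repeats = {ec: spec.repeats_for(gi, ec) for ec in spec.all_ecs()}
            for attempt in range(20):
                genome, expected = _build_genome(
                    genome_id, spec, spec.genes_for(gi), repeats, group_sp_sets[taxon], rng
                )
                # ground-truth closure: accept only if the full-genome scan
                # reproduces the planted counts exactly
                _, table = scan_reads(
                    [ShortRead(genome_id, genome.sequence)], matcher, collect_hits=True
                )
                observed: dict[str, int] = {}
                for cat, counter in table.sp_counts.items():
                    for sp, n in counter.items():
                        observed[sp] = observed.get(sp, 0) + n
                if observed == expected:
                    break
            else:
                raise RuntimeError(f"could not assemble clean genome {genome_id}")
            genomes.append(genome)
            sp_counts[genome_id] = expected

    enzyme_counts = {g.genome_id: g.enzyme_counts for g in genomes}
    pooled: dict[str, int] = {}
    for counts in enzyme_counts.values():
        for k, v in counts.items():
            pooled[k] = pooled.get(k, 0) + v
    # asymptotic RF per level-3 category: planted SP occurrences per gene,
    # pooled over genomes (gene-count weighted when densities vary)
    num: dict[str, int] = {}
    den: dict[str, int] = {}
    for gi in range(spec.n_genomes):
        for ec_text, n in spec.genes_for(gi).items():
            cat = str(ECLabel.parse(ec_text).level3())
            num[cat] = num.get(cat, 0) + n * spec.repeats_for(gi, ec_text) * spec.sps_per_gene
            den[cat] = den.get(cat, 0) + n
    asymptotic = {cat: num[cat] / den[cat] for cat in num if den[cat] > 0}
    taxon_enzymes: dict[str, int] = {}
    if spec.taxon_assignment:
        for taxon, members in groups.items():
            if taxon is not None:
                taxon_enzymes[taxon] = sum(
                    sum(spec.genes_for(gi).values()) for gi in members
                )
    truth = FixtureTruth(enzyme_counts, pooled, asymptotic, taxon_enzymes, sp_counts)
    return Fixture(genomes, dictionary, truth)


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write genomes as FASTA + annotation TSVs and the dictionary TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in fixture.genomes:
        with open(outdir / f"{g.genome_id}.fasta", "w") as fh:
            fh.write(f">{g.genome_id}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i : i + 70] + "\n")
        save_annotation(g.genes, outdir / f"{g.genome_id}.annotation.tsv")
    save_dictionary(fixture.dictionary, outdir / "sp_dictionary.tsv")
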