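"""Dictionaries of Specific Peptides (SPs) and Taxon-Specific Peptides (TSPs).

A Specific Peptide is a short amino-acid string (here >= 7 residues) whose
verbatim presence in a protein sequence marks a specific enzymatic function in
the Enzyme Commission (EC) hierarchy.  A Taxon-Specific Peptide is an SP
(drawn from the aminoacyl-tRNA synthetases, EC 6.1.1.x) that occurs only in
proteins of a single taxon at a given rank, and therefore doubles as a
taxonomic marker.

The on-disk format is a headered TSV with columns
``peptide  ec  [taxon_rank  taxon_name]``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "AMINO_ACIDS",
    "ECLabel",
    "TaxonLabel",
    "SpecificPeptide",
    "SPDictionary",
    "DictionaryFormatError",
    "load_dictionary",
    "load_demo_dictionary",
    "save_dictionary",
    "redundancy_filter",
    "subset_by_taxon",
    "TAXON_REGISTRY",
    "RANKS",
]

#: The 20 standard amino acids.  Ambiguity codes (B, Z, J, X), selenocysteine
#: (U) and pyrrolysine (O) are rejected in SP sequences: SPs derive from
#: curated enzyme entries and an exact matcher gains nothing from wildcards.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

RANKS = ("kingdom", "phylum", "class", "order")


class DictionaryFormatError(ValueError):
    """A dictionary record failed validation; the message names the record."""


@dataclass(frozen=True, order=True)
class ECLabel:
    """An Enzyme Commission label of 3 or 4 numeric components, e.g. 6.1.1.4.

    Level-3 labels name a sub-subclass (e.g. 6.1.1, the aminoacyl-tRNA
    synthetases); level-4 labels name an individual activity.  Spectra are
    reported at level 3, so :meth:`level3` is the aggregation key used
    throughout.
    """

    components: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.components) not in (3, 4):
            raise ValueError(f"EC label needs 3 or 4 components, got {self.components!r}")
        if any((not isinstance(c, int)) or c < 1 for c in self.components):
            raise ValueError(f"EC components must be positive integers: {self.components!r}")

    @classmethod
    def parse(cls, text: str) -> "ECLabel":
        try:
            parts = tuple(int(p) for p in text.strip().split("."))
        except ValueError as exc:
            raise ValueError(f"unparsable EC label {text!r}") from exc
        return cls(parts)

    @property
    def level(self) -> int:
        return len(self.components)

    def level3(self) -> "ECLabel":
        """Truncate to the first three components (identity for level-3 labels)."""
        return ECLabel(self.components[:3])

    def __str__(self) -> str:
        return ".".join(str(c) for c in self.components)


# Known taxa of the S61 calibration: name -> (rank, lineage from kingdom down,
# excluding the taxon itself).  Rank is assigned by depth; Bacillales and
# Chroococcales are taxonomic orders but occupy the class slot of the 3-level
# calibration hierarchy and are treated at that level.
TAXON_REGISTRY: dict[str, tuple[str, tuple[str, ...]]] = {
    "Archaea": ("kingdom", ()),
    "Eukaryota": ("kingdom", ()),
    "Bacteria": ("kingdom", ()),
    "Proteobacteria": ("phylum", ("Bacteria",)),
    "Firmicutes": ("phylum", ("Bacteria",)),
    "Cyanobacteria": ("phylum", ("Bacteria",)),
    "Actinobacteria": ("phylum", ("Bacteria",)),
    "Tenericutes": ("phylum", ("Bacteria",)),
    "Bacteroidetes": ("phylum", ("Bacteria",)),
    "Spirochaetes": ("phylum", ("Bacteria",)),
    "Thermotogae": ("phylum", ("Bacteria",)),
    "Chlamydiae": ("phylum", ("Bacteria",)),
    "Chlorobi": ("phylum", ("Bacteria",)),
    "Aquificae": ("phylum", ("Bacteria",)),
    "Crenarchaeota": ("phylum", ("Archaea",)),
    "Euryarchaeota": ("phylum", ("Archaea",)),
    "Gammaproteobacteria": ("class", ("Bacteria", "Proteobacteria")),
    "Alphaproteobacteria": ("class", ("Bacteria", "Proteobacteria")),
    "Betaproteobacteria": ("class", ("Bacteria", "Proteobacteria")),
    "Epsilonproteobacteria": ("class", ("Bacteria", "Proteobacteria")),
    "Deltaproteobacteria": ("class", ("Bacteria", "Proteobacteria")),
    "Bacillales": ("class", ("Bacteria", "Firmicutes")),
    "Clostridia": ("class", ("Bacteria", "Firmicutes")),
    "Lactobacillales": ("class", ("Bacteria", "Firmicutes")),
    "Chroococcales": ("class", ("Bacteria", "Cyanobacteria")),
    "Bacteroidia": ("class", ("Bacteria", "Bacteroidetes")),
}


@dataclass(frozen=True, order=True)
class TaxonLabel:
    """A taxon at one of the supported ranks, with its ancestor lineage."""

    rank: str
    name: str
    lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}; expected one of {RANKS}")
        known = TAXON_REGISTRY.get(self.name)
        if known is None:
            raise ValueError(
                f"taxon {self.name!r} is not in the S61 registry "
                f"(known: {sorted(TAXON_REGISTRY)})"
            )
        if known is not None:
            rank, lineage = known
            if rank != self.rank:
                raise ValueError(
                    f"taxon {self.name!r} has rank {rank!r} in the registry, not {self.rank!r}"
                )
            if self.lineage and self.lineage != lineage:
                raise ValueError(
                    f"lineage {self.lineage!r} inconsistent with registry {lineage!r}"
                )
            if not self.lineage:
                object.__setattr__(self, "lineage", lineage)

    @classmethod
    def from_name(cls, name: str) -> "TaxonLabel":
        """Look up a registered taxon by name alone."""
        try:
            rank, lineage = TAXON_REGISTRY[name]
        except KeyError as exc:
            raise KeyError(f"taxon {name!r} is not in the S61 registry") from exc
        return cls(rank, name, lineage)


@dataclass(frozen=True, order=True)
class SpecificPeptide:
    """An amino-acid string labelled with an EC category and optionally a taxon."""

    sequence: str
    ec: ECLabel
    taxon: TaxonLabel | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - AMINO_ACIDS
        if bad or not self.sequence:
            raise ValueError(
                f"invalid amino-acid letter(s) {sorted(bad)!r} in SP {self.sequence!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SPDictionary:
    """A set of Specific Peptides plus free-text provenance metadata."""

    peptides: frozenset[SpecificPeptide]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[SpecificPeptide]:
        return iter(self.peptides)

    @property
    def has_taxa(self) -> bool:
        return any(p.taxon is not None for p in self.peptides)

    def by_sequence(self) -> dict[str, list[SpecificPeptide]]:
        out: dict[str, list[SpecificPeptide]] = {}
        for p in sorted(self.peptides):
            out.setdefault(p.sequence, []).append(p)
        return out


def load_dictionary(path: str | Path, min_length: int = 7) -> SPDictionary:
    """Read an SP dictionary TSV, keeping peptides of length >= ``min_length``.

    Malformed lines raise :class:`DictionaryFormatError` naming the line
    number.  The header line is required.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    path = Path(path)
    peptides: set[SpecificPeptide] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "peptide":
            raise DictionaryFormatError(f"{path}: missing 'peptide ...' header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DictionaryFormatError(f"{path}:{lineno}: expected >= 2 columns")
            seq, ec_text = fields[0].strip().upper(), fields[1]
            taxon: TaxonLabel | None = None
            if len(fields) >= 4 and fields[2].strip():
                taxon = TaxonLabel(fields[2].strip(), fields[3].strip())
            try:
                sp = SpecificPeptide(seq, ECLabel.parse(ec_text), taxon)
            except ValueError as exc:
                raise DictionaryFormatError(f"{path}:{lineno}: {exc}") from exc
            if len(sp) >= min_length:
                peptides.add(sp)
    return SPDictionary(frozenset(peptides), provenance=f"loaded from {path}")


def load_demo_dictionary(min_length: int = 7) -> SPDictionary:
    """The small demonstration dictionary shipped with the package."""
    ref = importlib.resources.files("spsr.data") / "demo_sp_dictionary.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_dictionary(path, min_length=min_length)


def save_dictionary(d: SPDictionary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tec\ttaxon_rank\ttaxon_name\n")
        for p in sorted(d.peptides):
            rank = p.taxon.rank if p.taxon else ""
            name = p.taxon.name if p.taxon else ""
            fh.write(f"{p.sequence}\t{p.ec}\t{rank}\t{name}\n")


def redundancy_filter(d: SPDictionary) -> SPDictionary:
    """Discard any SP that contains, as a substring, a shorter SP with the
    same EC label.

    Equal-length duplicates with different EC labels are both retained: the
    rule removes supersequences of strictly shorter same-EC peptides only.
    Idempotent, and never increases the dictionary size.
    """
    by_ec: dict[ECLabel, list[SpecificPeptide]] = {}
    for p in d.peptides:
        by_ec.setdefault(p.ec, []).append(p)
    kept: set[SpecificPeptide] = set()
    for peps in by_ec.values():
        peps.sort(key=lambda p: (len(p.sequence), p.sequence))
        for i, p in enumerate(peps):
            # only strictly shorter same-EC peptides can eliminate p
            if any(
                len(q.sequence) < len(p.sequence) and q.sequence in p.sequence
                for q in peps[:i]
            ):
                continue
            kept.add(p)
    return SPDictionary(frozenset(kept), provenance=d.provenance)


def subset_by_taxon(d: SPDictionary, ranks: Iterable[str]) -> SPDictionary:
    """Keep only peptides whose taxon rank is in ``ranks``.

    Raises ``ValueError`` on a dictionary that carries no taxon labels at all,
    since the request is then meaningless.
    """
    ranks = set(ranks)
    unknown = ranks - set(RANKS)
    if unknown:
        raise ValueError(f"unknown rank(s) {sorted(unknown)!r}")
    if not d.has_taxa:
        raise ValueError("dictionary carries no taxon labels; cannot subset by taxon")
    kept = frozenset(p for p in d.peptides if p.taxon is not None and p.taxon.rank in ranks)
    return SPDictionary(kept, provenance=d.provenance)
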