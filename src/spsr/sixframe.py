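"""Six-frame translation of short reads into pseudo-peptide candidates.

Assembly-free functional profiling does not know the coding frame or strand
of a read, so every read is translated in all six ways (3 frames x 2
strands).  Stop codons become ``'*'`` and are deliberately NOT used to split
the peptide: SP sequences never contain ``'*'``, so an exact match can never
span a stop, which reproduces the contained-in-frame contract without any ORF
calling.  Codons containing ``N`` translate to ``'X'``, which likewise never
matches an SP letter.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "ShortRead",
    "PseudoPeptide",
    "PseudoPeptideSet",
    "reverse_complement",
    "translate_frame",
    "translate_read",
    "read_sequences",
    "DESIGN_BAND_NT",
]

log = logging.getLogger(__name__)

#: Read-length band the factor calibration is designed for (nucleotides).
#: Reads outside it are still processed, with a warning.
DESIGN_BAND_NT = (50, 200)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Codon -> amino acid, from the standard genetic code (NCBI table 1).
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, with N -> N."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide letter(s) {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ShortRead:
    """A nucleotide read.  Sequence is uppercased; qualities are ignored."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.id!r}: invalid letter(s) {sorted(bad)!r}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PseudoPeptide:
    """One of the six translations of a read."""

    strand: str  # '+' or '-'
    frame: int  # 0, 1 or 2: number of bases skipped at the 5' end
    peptide: str


@dataclass(frozen=True)
class PseudoPeptideSet:
    read_id: str
    peptides: tuple[PseudoPeptide, ...]

    def __iter__(self) -> Iterator[PseudoPeptide]:
        return iter(self.peptides)


def translate_frame(seq: str, frame: int) -> str:
    """Translate one frame of ``seq``; length is floor((len - frame)/3)."""
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def translate_read(read: ShortRead) -> PseudoPeptideSet:
    """All six pseudo-peptides of a read (3 frames on each strand)."""
    fwd = read.sequence
    rev = reverse_complement(fwd)
    peptides = tuple(
        PseudoPeptide(strand, frame, translate_frame(seq, frame))
        for strand, seq in (("+", fwd), ("-", rev))
        for frame in (0, 1, 2)
    )
    return PseudoPeptideSet(read.id, peptides)


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: Path) -> str:
    name = path.name[: -len(".gz")] if path.suffix == ".gz" else path.name
    ext = Path(name).suffix.lower()
    if ext in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[ShortRead]:
    """Stream reads from a FASTA or FASTQ file (plain or gzipped).

    Format is inferred from the extension unless ``fmt`` is given.  Warns
    (once) about reads outside the supported length band.
    """
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    warned = False
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            read = ShortRead(rec.id, str(rec.seq))
            lo, hi = DESIGN_BAND_NT
            if not warned and not (lo <= read.length_nt <= hi):
                log.warning(
                    "read %s is %d nt, outside the calibrated band %d-%d nt",
                    read.id, read.length_nt, lo, hi,
                )
                warned = True
            yield read


def read_genome(path: str | Path) -> str:
    """Concatenated sequence of a (possibly multi-record) genome FASTA."""
    path = Path(path)
    with _open_maybe_gzip(path) as fh:
        return "".join(str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta"))


def expected_frame_length(read_length_nt: int, frame: int) -> int:
    """Residues in a frame-``frame`` translation of a ``read_length_nt`` read."""
    return max(0, math.floor((read_length_nt - frame) / 3))
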