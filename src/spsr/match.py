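"""Exact multi-pattern SP matching on six-frame pseudo-peptides.

Every occurrence of every dictionary peptide on every one of a read's six
pseudo-peptides is a hit — including overlapping occurrences and repeats of
one SP on one read.  Hits are tallied either per EC level-3 category (the
enzymatic spectrum key) or per taxon name (for TSP dictionaries).

The matcher is an Aho-Corasick automaton: a trie of the patterns with
failure links, scanning each text in a single pass, linear in text length
plus number of hits.  Its hit set is verified against a naive all-positions
scan in the test suite.
"""

from __future__ import annotations

import json
from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

from .sixframe import ShortRead, translate_read
from .sp_dictionary import ECLabel, SPDictionary, SpecificPeptide, TaxonLabel

__all__ = [
    "AhoCorasick",
    "Matcher",
    "SPHit",
    "HitTable",
    "AnomalyReport",
    "build_matcher",
    "scan_reads",
    "flag_anomalies",
    "write_hits_tsv",
]


class AhoCorasick:
    """Multi-pattern exact matcher over arbitrary strings.

    ``find(text)`` yields ``(pattern_index, offset)`` for every occurrence,
    overlapping ones included.
    """

    def __init__(self, patterns: Iterable[str]):
        self.patterns: list[str] = list(patterns)
        if not self.patterns:
            raise ValueError("cannot build a matcher from an empty pattern set")
        if any(not p for p in self.patterns):
            raise ValueError("empty pattern")
        # trie: goto[node] maps character -> node
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[int]] = [[]]
        for idx, pat in enumerate(self.patterns):
            node = 0
            for ch in pat:
                nxt = self._goto[node].get(ch)
                if nxt is None:
                    nxt = len(self._goto)
                    self._goto[node][ch] = nxt
                    self._goto.append({})
                    self._out.append([])
                node = nxt
            self._out[node].append(idx)
        # failure links by BFS; output sets are merged along them so every
        # node knows all patterns ending at its position
        self._fail = [0] * len(self._goto)
        queue: deque[int] = deque()
        for node in self._goto[0].values():
            queue.append(node)
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def find(self, text: str) -> Iterator[tuple[int, int]]:
        goto, fail, out = self._goto, self._fail, self._out
        node = 0
        for pos, ch in enumerate(text):
            while node and ch not in goto[node]:
                node = fail[node]
            node = goto[node].get(ch, 0)
            for idx in out[node]:
                yield idx, pos - len(self.patterns[idx]) + 1


@dataclass
class Matcher:
    """An automaton bound to the dictionary it was built from."""

    automaton: AhoCorasick
    entries: list[list[SpecificPeptide]]  # per pattern index: peptides sharing that sequence

    @property
    def n_sequences(self) -> int:
        return len(self.entries)


def build_matcher(dictionary: SPDictionary) -> Matcher:
    """Compile a dictionary into a reusable multi-pattern matcher."""
    if len(dictionary) == 0:
        raise ValueError("cannot build a matcher from an empty SP dictionary")
    by_seq = dictionary.by_sequence()
    sequences = sorted(by_seq)
    return Matcher(AhoCorasick(sequences), [by_seq[s] for s in sequences])


@dataclass(frozen=True)
class SPHit:
    """One verbatim SP occurrence inside one pseudo-peptide."""

    read_id: str
    sp_sequence: str
    ec: ECLabel
    taxon: TaxonLabel | None
    strand: str
    frame: int
    offset_aa: int


def _key_ec3(hit: SPHit) -> str:
    return str(hit.ec.level3())


def _key_taxon(hit: SPHit) -> str | None:
    return hit.taxon.name if hit.taxon else None


_KEY_FUNCS: dict[str, Callable[[SPHit], str | None]] = {
    "ec3": _key_ec3,
    "taxon": _key_taxon,
}


@dataclass
class HitTable:
    """Aggregated SP hit counts over a read set.

    ``counts`` is keyed by EC level-3 string (enzymatic mode) or taxon name
    (taxonomic mode).  ``sp_counts`` keeps, per category, the count of each
    distinct supporting SP sequence — the anomaly detector needs it.
    """

    counts: dict[str, int] = field(default_factory=dict)
    sp_counts: dict[str, Counter] = field(default_factory=dict)
    n_reads: int = 0
    mean_read_length: float = 0.0
    min_read_length: int = 0
    max_read_length: int = 0
    cv_read_length: float = 0.0
    key: str = "ec3"

    @property
    def total_hits(self) -> int:
        return sum(self.counts.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "key": self.key,
            "n_reads": self.n_reads,
            "read_length": {
                "mean": self.mean_read_length,
                "min": self.min_read_length,
                "max": self.max_read_length,
                "cv": self.cv_read_length,
            },
            "counts": dict(sorted(self.counts.items())),
            "sp_counts": {k: dict(v) for k, v in sorted(self.sp_counts.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\thits\tn_distinct_sps\n")
            for cat in sorted(self.counts):
                fh.write(f"{cat}\t{self.counts[cat]}\t{len(self.sp_counts.get(cat, ()))}\n")


def scan_reads(
    reads: Iterable[ShortRead],
    matcher: Matcher,
    key: str = "ec3",
    collect_hits: bool = True,
) -> tuple[list[SPHit], HitTable]:
    """Scan reads for SP hits and aggregate a :class:`HitTable`.

    Deterministic given the input order.  With ``collect_hits=False`` the
    per-hit list is not kept (saves memory on large runs); the table is
    always complete.
    """
    if key not in _KEY_FUNCS:
        raise ValueError(f"unknown aggregation key {key!r}; expected one of {sorted(_KEY_FUNCS)}")
    keyfn = _KEY_FUNCS[key]
    hits: list[SPHit] = []
    table = HitTable(key=key)
    n = 0
    length_sum = 0.0
    length_sumsq = 0.0
    lmin, lmax = None, 0
    for read in reads:
        n += 1
        k = read.length_nt
        length_sum += k
        length_sumsq += k * k
        lmin = k if lmin is None else min(lmin, k)
        lmax = max(lmax, k)
        for pp in translate_read(read):
            for pat_idx, offset in matcher.automaton.find(pp.peptide):
                for entry in matcher.entries[pat_idx]:
                    hit = SPHit(
                        read.id, entry.sequence, entry.ec, entry.taxon,
                        pp.strand, pp.frame, offset,
                    )
                    if collect_hits:
                        hits.append(hit)
                    cat = keyfn(hit)
                    if cat is None:
                        continue
                    table.counts[cat] = table.counts.get(cat, 0) + 1
                    table.sp_counts.setdefault(cat, Counter())[entry.sequence] += 1
    table.n_reads = n
    if n:
        mean = length_sum / n
        var = max(0.0, length_sumsq / n - mean * mean)
        table.mean_read_length = mean
        table.min_read_length = lmin or 0
        table.max_read_length = lmax
        table.cv_read_length = (var ** 0.5) / mean if mean else 0.0
    return hits, table


@dataclass(frozen=True)
class AnomalyReport:
    """An EC category whose signal is suspiciously concentrated.

    A category that out-counts every other category by more than ``fold``
    while being supported by at most ``max_support`` distinct SP sequences is
    more plausibly a data artifact (e.g. one over-amplified fragment) than a
    genuine functional signal.
    """

    category: str
    count: int
    next_largest: int
    supporting_sps: tuple[str, ...]


def flag_anomalies(
    table: HitTable,
    fold: float = 10.0,
    max_support: int = 2,
) -> list[AnomalyReport]:
    """Flag dominated, narrowly-supported categories (see :class:`AnomalyReport`).

    A single-category table yields no anomaly: there is no comparator.
    """
    if len(table.counts) < 2:
        return []
    ordered = sorted(table.counts.items(), key=lambda kv: kv[1], reverse=True)
    reports: list[AnomalyReport] = []
    for i, (cat, count) in enumerate(ordered):
        next_largest = ordered[1][1] if i == 0 else ordered[0][1]
        supports = table.sp_counts.get(cat, Counter())
        if count > fold * next_largest and len(supports) <= max_support:
            reports.append(
                AnomalyReport(cat, count, next_largest, tuple(sorted(supports)))
            )
    return reports


def write_hits_tsv(hits: Iterable[SPHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsp\tec\ttaxon\tstrand\tframe\toffset_aa\n")
        for h in hits:
            taxon = h.taxon.name if h.taxon else ""
            fh.write(
                f"{h.read_id}\t{h.sp_sequence}\t{h.ec}\t{taxon}\t"
                f"{h.strand}\t{h.frame}\t{h.offset_aa}\n"
            )
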