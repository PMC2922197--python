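"""Taxonomic classification from Taxon-Specific Peptides of the aaRS family.

The aminoacyl-tRNA synthetases (EC 6.1.1.x) are near-universal and, for most
of their 4th-level categories, single-copy per bacterial species.  The S61
subset keeps only those categories with at most 2% multiple entries per
species, so that TSP hit counts can be converted to predicted enzyme — hence
cell — numbers.  Per-taxon raw factors correct for the very unequal sizes of
TSP pools across taxa; without them, hit counts would measure database
coverage rather than community composition.

The packaged factor table was calibrated on curated proteome data and should
be read as a lower bound: environmental proteins unknown to the reference
database carry fewer TSP hits per enzyme.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .match import HitTable
from .sp_dictionary import TAXON_REGISTRY, ECLabel

_RANK_CACHE = {name: rank for name, (rank, _) in TAXON_REGISTRY.items()}

__all__ = [
    "AarsMultiplicity",
    "TaxonFactorRow",
    "TaxonFactorTable",
    "TaxonMixture",
    "percent_multiples",
    "select_s61",
    "predict_taxon_mixture",
    "precision",
    "load_aars_multiplicity",
    "load_taxon_factors",
    "write_mixture_report",
]

LOWER_BOUND_CAVEAT = (
    "Factors calibrated on curated proteomes; predicted enzyme numbers are "
    "lower-bound estimates for environmental data."
)


@dataclass(frozen=True)
class AarsMultiplicity:
    """Per-species multiplicity statistics for one aaRS level-4 category.

    ``doublets``/``triplets`` count species contributing 2/3 entries;
    ``proteins`` is the total number of proteins in the category.
    """

    ec4: ECLabel
    doublets: int
    triplets: int
    proteins: int

    def __post_init__(self) -> None:
        if self.ec4.level != 4:
            raise ValueError(f"expected a level-4 EC label, got {self.ec4}")
        if 2 * self.doublets + 3 * self.triplets > self.proteins:
            raise ValueError(
                f"{self.ec4}: multiples exceed total proteins "
                f"({self.doublets} doublets, {self.triplets} triplets, {self.proteins} proteins)"
            )


def percent_multiples(row: AarsMultiplicity) -> float:
    """Percentage of proteins that are surplus copies: 100*(doublets + 2*triplets)/proteins.

    A doublet species contributes one surplus protein, a triplet species two.
    """
    if row.proteins <= 0:
        raise ValueError(f"{row.ec4}: proteins must be > 0")
    return 100.0 * (row.doublets + 2 * row.triplets) / row.proteins


def select_s61(
    rows: list[AarsMultiplicity],
    threshold_percent: float = 2.0,
) -> set[ECLabel]:
    """The single-copy aaRS subset: categories with <= threshold % multiples.

    The percentage is rounded to 1 decimal before comparison, so a category
    at 2.03% (rounding to 2.0) passes the default 2% threshold.
    """
    if threshold_percent < 0:
        raise ValueError("threshold must be non-negative")
    return {
        r.ec4 for r in rows if round(percent_multiples(r), 1) <= threshold_percent
    }


@dataclass(frozen=True)
class TaxonFactorRow:
    parent: str
    taxon: str
    n_enzymes: int
    n_tsps: int
    n_hits: int
    factor: float


@dataclass
class TaxonFactorTable:
    """Per-taxon raw factors for the S61 TSP set (hits per enzyme)."""

    rows: list[TaxonFactorRow]

    def factor_for(self, taxon: str) -> float | None:
        for r in self.rows:
            if r.taxon == taxon:
                return r.factor
        return None

    def taxa_at(self, rank: str) -> list[str]:
        return [
            r.taxon
            for r in self.rows
            if r.taxon in _RANK_CACHE and _RANK_CACHE[r.taxon] == rank
        ]



@dataclass
class TaxonMixture:
    """Predicted enzyme numbers per taxon at one rank, with the no-call rule.

    Taxa whose predicted enzyme number falls below ``no_call_threshold`` are
    not assigned (``no_call``); taxa with hits but no factor at all cannot be
    predicted (``no_prediction``).  ``percent_among_called`` reports the
    mixture over assigned taxa only.
    """

    level: str
    predicted_enzymes: dict[str, float]
    no_call: set[str] = field(default_factory=set)
    no_prediction: set[str] = field(default_factory=set)
    caveat: str = LOWER_BOUND_CAVEAT

    @property
    def percent_among_called(self) -> dict[str, float]:
        total = sum(self.predicted_enzymes.values())
        if total <= 0:
            return {}
        return {t: 100.0 * v / total for t, v in self.predicted_enzymes.items()}


def predict_taxon_mixture(
    hits: HitTable,
    factors: TaxonFactorTable,
    level: str,
    no_call_threshold: float = 1.0,
) -> TaxonMixture:
    """Convert taxon-keyed TSP hit counts to a predicted taxon mixture.

    ``predicted[taxon] = hits[taxon] / factor[taxon]``, applied to taxa of
    the requested rank.  The no-call threshold is applied to the unrounded
    prediction.
    """
    if hits.key != "taxon":
        raise ValueError("hit table must be aggregated by taxon (key='taxon')")
    mixture = TaxonMixture(level, {})
    for taxon, count in sorted(hits.counts.items()):
        if _RANK_CACHE.get(taxon) != level:
            continue
        factor = factors.factor_for(taxon)
        if factor is None or factor <= 0:
            mixture.no_prediction.add(taxon)
            continue
        predicted = count / factor
        if predicted < no_call_threshold:
            mixture.no_call.add(taxon)
        else:
            mixture.predicted_enzymes[taxon] = predicted
    return mixture


def precision(tp: float, fp: float) -> float:
    """Percent precision, 100*TP/(TP+FP); undefined when both are zero."""
    if tp < 0 or fp < 0:
        raise ValueError("TP and FP must be non-negative")
    if tp + fp == 0:
        raise ValueError("precision undefined: TP + FP is zero")
    return 100.0 * tp / (tp + fp)


def load_aars_multiplicity() -> list[AarsMultiplicity]:
    """The packaged aaRS multiplicity statistics (counts per level-4 category)."""
    ref = importlib.resources.files("spsr.data") / "aars_multiplicity.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"ec": str})
    return [
        AarsMultiplicity(
            ECLabel.parse(r.ec), int(r.doublets), int(r.triplets), int(r.proteins)
        )
        for r in df.itertuples()
    ]


def load_taxon_factors(path: str | Path | None = None) -> TaxonFactorTable:
    """Taxon factor table; defaults to the packaged S61 calibration."""
    if path is None:
        ref = importlib.resources.files("spsr.data") / "taxon_factors_s61.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_taxon_factors(p)
    df = pd.read_csv(path, sep="\t", dtype={"parent": str, "taxon": str})
    rows = [
        TaxonFactorRow(
            "" if pd.isna(r.parent) else r.parent,
            r.taxon,
            int(r.n_enzymes),
            int(r.n_tsps),
            int(r.n_hits),
            float(r.factor),
        )
        for r in df.itertuples()
    ]
    return TaxonFactorTable(rows)


def write_mixture_report(
    mixtures: list[TaxonMixture],
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
    hits: HitTable | None = None,
    factors: TaxonFactorTable | None = None,
) -> None:
    rows = []
    for m in mixtures:
        pct = m.percent_among_called
        for taxon in sorted(set(m.predicted_enzymes) | m.no_call | m.no_prediction):
            status = (
                "called" if taxon in m.predicted_enzymes
                else "no_call" if taxon in m.no_call
                else "no_prediction"
            )
            rows.append(
                {
                    "level": m.level,
                    "taxon": taxon,
                    "hits": hits.counts.get(taxon, 0) if hits else None,
                    "factor": factors.factor_for(taxon) if factors else None,
                    "predicted": m.predicted_enzymes.get(taxon),
                    "percent_among_called": pct.get(taxon),
                    "status": status,
                }
            )
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("level\ttaxon\thits\tfactor\tpredicted\tpercent_among_called\tstatus\n")
            for r in rows:
                fh.write(
                    "\t".join(
                        "" if r[k] is None else (f"{r[k]:.4g}" if isinstance(r[k], float) else str(r[k]))
                        for k in (
                            "level", "taxon", "hits", "factor",
                            "predicted", "percent_among_called", "status",
                        )
                    )
                    + "\n"
                )
    if json_path is not None:
        payload = {"caveat": LOWER_BOUND_CAVEAT, "rows": rows}
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
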