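"""Enzymatic spectra: from SP hit counts to predicted enzyme-gene numbers.

``predicted[EC] = hits[EC] / RF(EC)`` converts category hit counts into
predicted numbers of enzyme genes (times coverage, for factors calibrated
per unit coverage).  Dividing by the reference category gives the relative
spectrum, which is robust to read length because normalized factors are.
Since the reference 6.1.1 (aminoacyl-tRNA synthetases) is essentially
single-copy with ~20 members per bacterial genome, the predicted 6.1.1 count
divided by 20 estimates the total cell (coverage) content of a metagenome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .calibrate import FactorTable
from .match import HitTable

__all__ = [
    "EnzymaticSpectrum",
    "FitStatistic",
    "predict_spectrum",
    "chi_square_fit",
    "cells_estimate",
    "write_spectrum_report",
]

log = logging.getLogger(__name__)

#: One aminoacyl-tRNA synthetase per amino acid.
DEFAULT_AARS_PER_GENOME = 20.0


@dataclass
class EnzymaticSpectrum:
    predicted: dict[str, float]
    relative: dict[str, float] | None
    uncalibrated: dict[str, int]
    read_length_nt: float | None
    factor_table_id: str = ""
    reference: str = "6.1.1"


@dataclass
class FitStatistic:
    """Chi-square agreement between predicted and known category counts.

    ``chi2_per_dof`` is the mean of ((predicted - known)/sd)^2 over the N
    compared categories; values of order 1 indicate predictions consistent
    with the calibration errors.
    """

    chi2_per_dof: float
    n_dof: int
    per_category_terms: dict[str, float] = field(default_factory=dict)


def predict_spectrum(hits: HitTable, factors: FactorTable) -> EnzymaticSpectrum:
    """Convert a hit table into absolute and relative predicted enzyme counts.

    Absolute predictions use raw factors; the relative spectrum divides by
    the reference category's prediction (equivalently, uses normalized
    factors).  Categories with hits but no calibrated factor are reported in
    ``uncalibrated`` rather than silently dropped.
    """
    if factors.read_length_nt is not None and hits.mean_read_length:
        if hits.cv_read_length > 0.20:
            log.warning(
                "read lengths are heterogeneous (CV %.0f%%); using factors for "
                "length %s against mean read length %.0f",
                100 * hits.cv_read_length, factors.read_length_nt, hits.mean_read_length,
            )
    predicted: dict[str, float] = {}
    uncalibrated: dict[str, int] = {}
    for cat, count in hits.counts.items():
        rf = factors.rf.get(cat)
        if rf is None or rf <= 0:
            uncalibrated[cat] = count
        else:
            predicted[cat] = count / rf
    relative: dict[str, float] | None = None
    ref_pred = predicted.get(factors.reference, 0.0)
    if ref_pred > 0:
        relative = {cat: v / ref_pred for cat, v in predicted.items()}
    else:
        log.warning(
            "reference category %s absent from hits; relative spectrum unavailable",
            factors.reference,
        )
    return EnzymaticSpectrum(
        predicted, relative, uncalibrated,
        hits.mean_read_length or factors.read_length_nt,
        factors.table_id, factors.reference,
    )


def chi_square_fit(
    predicted: dict[str, float],
    known: dict[str, float],
    sd: dict[str, float],
) -> FitStatistic:
    """Mean squared standardized deviation over the compared categories.

    For predictions consistent with the calibration errors the statistic is
    of the order of 1 per degree of freedom.  Compares the intersection of
    the ``predicted`` and ``known`` keys.
    """
    terms: dict[str, float] = {}
    for cat in sorted(set(predicted) & set(known)):
        s = sd.get(cat, 0.0)
        diff = predicted[cat] - known[cat]
        if s == 0:
            if diff != 0:
                raise ValueError(f"category {cat}: sd is 0 but predicted != known")
            terms[cat] = 0.0
        else:
            terms[cat] = (diff / s) ** 2
    n = len(terms)
    if n == 0:
        raise ValueError("no categories in common between predicted and known")
    return FitStatistic(sum(terms.values()) / n, n, terms)


def cells_estimate(
    spectrum: EnzymaticSpectrum,
    aars_per_genome: float = DEFAULT_AARS_PER_GENOME,
) -> float:
    """Total cell (coverage) content: predicted reference count / aaRS per genome."""
    return spectrum.predicted.get(spectrum.reference, 0.0) / aars_per_genome


def write_spectrum_report(
    spectrum: EnzymaticSpectrum,
    hits: HitTable,
    factors: FactorTable,
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
    relative_only: bool = False,
) -> None:
    rows = []
    for cat in sorted(set(spectrum.predicted) | set(spectrum.uncalibrated)):
        rows.append(
            {
                "ec": cat,
                "hits": hits.counts.get(cat, 0),
                "rf_used": factors.rf.get(cat),
                "predicted": None if relative_only else spectrum.predicted.get(cat),
                "relative": (spectrum.relative or {}).get(cat),
            }
        )
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("ec\thits\trf_used\tpredicted\trelative\n")
            for r in rows:
                vals = [
                    r["ec"], r["hits"],
                    "" if r["rf_used"] is None else f"{r['rf_used']:.6g}",
                    "" if r["predicted"] is None else f"{r['predicted']:.6g}",
                    "" if r["relative"] is None else f"{r['relative']:.6g}",
                ]
                fh.write("\t".join(str(v) for v in vals) + "\n")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")
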