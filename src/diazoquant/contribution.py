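"""Scaling symbiosis abundance by single-cell rates to a share of bulk fixation.

Microscopy counts of FISH-positive diatom symbioses on a filter piece are
converted to volumetric abundances (symbioses L-1), multiplied by a mean
single-cell N2-fixation rate (fmol N symbiosis-1 d-1) to give a volumetric
contribution (nmol N L-1 d-1), and expressed as a percentage of the
measured bulk rate. Expected nifH gene-copy numbers (abundance x symbionts
per host x copies per symbiont genome) are cross-checked against a qPCR
limit of quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import pandas as pd

__all__ = [
    "FilterCount",
    "ContributionEstimate",
    "abundance",
    "contribution",
    "fraction_of_bulk",
    "expected_gene_copies",
    "quantifiability",
    "round_table",
    "contribution_table",
]

FMOL_PER_NMOL = 1e6


@dataclass(frozen=True)
class FilterCount:
    """FISH-positive symbioses counted on a piece of a sample filter.

    ``equiv_volume_l`` is the seawater volume the examined filter area
    represents. It can be given directly or derived from the piece area,
    the effective filtration area (excluding the filtration-tower rim) and
    the filtered volume via :meth:`from_areas`.
    """

    station: str
    depth_m: float
    count: int
    equiv_volume_l: float

    def __post_init__(self) -> None:
        if self.count < 0 or self.count != int(self.count):
            raise ValueError(f"count must be a non-negative integer, got {self.count}")
        if not self.equiv_volume_l > 0:
            raise ValueError(f"equivalent volume must be > 0 L, got {self.equiv_volume_l}")

    @classmethod
    def from_areas(
        cls,
        station: str,
        depth_m: float,
        count: int,
        piece_area_mm2: float,
        effective_filter_area_mm2: float,
        filtered_volume_l: float,
    ) -> "FilterCount":
        if not 0 < piece_area_mm2 <= effective_filter_area_mm2:
            raise ValueError(
                "require 0 < piece_area <= effective_filter_area, got "
                f"{piece_area_mm2} vs {effective_filter_area_mm2}"
            )
        equiv = filtered_volume_l * piece_area_mm2 / effective_filter_area_mm2
        return cls(station, depth_m, count, equiv)


@dataclass(frozen=True)
class ContributionEstimate:
    station: str
    depth_m: float
    abundance_per_l: float
    contribution_nmol_l_d: float
    fraction_pct: float          # NaN when the bulk rate is undetected/zero
    expected_copies_per_l: float


def abundance(fc: FilterCount) -> float:
    """Volumetric abundance, symbioses L-1 (unrounded)."""
    return fc.count / fc.equiv_volume_l


def contribution(abundance_per_l: float, mean_rate_fmol: float) -> float:
    """Volumetric contribution, nmol N L-1 d-1.

    abundance (symbioses L-1) x mean single-cell rate (fmol N symb-1 d-1),
    converted fmol -> nmol.
    """
    if abundance_per_l < 0 or mean_rate_fmol < 0:
        raise ValueError("abundance and mean rate must be >= 0")
    return abundance_per_l * mean_rate_fmol / FMOL_PER_NMOL


def fraction_of_bulk(
    contribution_nmol_l_d: float, bulk_rate_mean: float, detected: bool = True
) -> float:
    """Contribution as % of the bulk rate; NaN when undefined.

    Undefined (flagged NaN) for undetected or non-positive bulk rates.
    """
    if not detected or not bulk_rate_mean > 0:
        return float("nan")
    return 100.0 * contribution_nmol_l_d / bulk_rate_mean


def expected_gene_copies(
    abundance_per_l: float, symbionts_per_host: int = 2, copies_per_symbiont: int = 1
) -> float:
    """Expected nifH copies L-1 implied by the microscopy counts."""
    if symbionts_per_host < 1 or copies_per_symbiont < 1:
        raise ValueError("symbionts_per_host and copies_per_symbiont must be >= 1")
    if abundance_per_l < 0:
        raise ValueError("abundance must be >= 0")
    return abundance_per_l * symbionts_per_host * copies_per_symbiont


def quantifiability(
    copies_per_l: float,
    loq_range: Sequence[float] = (120.0, 180.0),
    marginal_factor: float = 2.0,
) -> str:
    """Classify a copy number against a qPCR limit-of-quantification range.

    Returns ``below_loq`` under the range, ``marginal`` inside it or within
    ``marginal_factor`` x the upper limit, else ``quantifiable``.
    """
    low, high = float(loq_range[0]), float(loq_range[1])
    if low > high:
        raise ValueError(f"LOQ range must satisfy low <= high, got [{low}, {high}]")
    if copies_per_l < low:
        return "below_loq"
    if copies_per_l <= high * marginal_factor:
        return "marginal"
    return "quantifiable"


def round_table(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, for printed-table style output."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def contribution_table(
    counts: Sequence[FilterCount],
    rates: pd.DataFrame,
    mean_rate_fmol: float,
    symbionts_per_host: int = 2,
    copies_per_symbiont: int = 1,
    depth_tolerance_m: float = 5.0,
) -> pd.DataFrame:
    """Join microscopy counts with bulk rates into a printed-table layout.

    ``rates`` is the output of :func:`diazoquant.bulk.rate_table`. Counts
    are matched to rates by station and by depth within
    ``depth_tolerance_m``; a count with no matching rate row keeps its
    abundance and contribution but gets NaN bulk fields and a
    ``rate_missing`` flag. Contribution is reported unrounded
    (``contribution``) and rounded half-away-from-zero to 2 decimals
    (``contribution_2dp``); the percentage uses the unrounded value.
    """
    rows = []
    for fc in counts:
        ab = abundance(fc)
        contrib = contribution(ab, mean_rate_fmol)
        match = rates[
            (rates["station"] == fc.station)
            & ((rates["depth_m"] - fc.depth_m).abs() <= depth_tolerance_m)
        ]
        if len(match) > 0:
            r = match.iloc[(match["depth_m"] - fc.depth_m).abs().values.argmin()]
            bulk_mean, bulk_sd = float(r["rate_mean"]), float(r["rate_sd"])
            detected = bool(r["detected"])
            missing = False
        else:
            bulk_mean = bulk_sd = float("nan")
            detected = False
            missing = True
        copies = expected_gene_copies(ab, symbionts_per_host, copies_per_symbiont)
        rows.append(
            {
                "station": fc.station,
                "depth_m": fc.depth_m,
                "bulk_rate_mean": bulk_mean,
                "bulk_rate_sd": bulk_sd,
                "bulk_detected": detected,
                "rate_missing": missing,
                "abundance_per_L": ab,
                "abundance_rounded": round(ab),
                "contribution": contrib,
                "contribution_2dp": round_table(contrib, 2),
                "fraction_pct": fraction_of_bulk(contrib, bulk_mean, detected)
                if not missing
                else float("nan"),
                "expected_copies_per_L": copies,
                "quantifiability": quantifiability(copies),
            }
        )
    return pd.DataFrame(rows)
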