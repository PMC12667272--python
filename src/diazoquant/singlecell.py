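"""Single-cell N2-fixation and growth rates from nanoSIMS ROI ion counts.

Each region of interest (ROI) drawn on a nanoSIMS ion image — one symbiont
cell or one host diatom — yields isotope atom fractions directly from the
secondary-ion counts:

    aN = c15N / (c15N + c14N),    aC = c13C / (c13C + c12C)

The N2-fixation rate of a cell converts its 15N enrichment above natural
abundance into newly fixed nitrogen via the cell's nitrogen quota:

    rate = (aN - a_nat_N) / (a_N2 - a_nat_N) * quota / t    [fmol N cell-1 d-1]

The quota comes from cell geometry: a pennate diatom is approximated as an
elliptic prism (V = pi/4 * L * W * H), carbon content follows a power law
pgC = a * V**b (diatom defaults a=0.288, b=0.811), and nitrogen is carbon
over a C:N ratio (Redfield 6.625 by default).

The 13C-based specific growth rate assumes exponential growth with new
biomass labelled at the DIC source enrichment, so the relative enrichment
approaches the source as 1 - exp(-mu*t); inverting:

    mu = -(1/t) * ln(1 - E/S),  E = aC - a_nat_C,  S = a_DIC - a_nat_C

A whole symbiosis (host diatom + its intracellular symbionts) fixes at the
sum of its parts' rates: fixed 15N transferred to the host shows up in the
host ROI and is counted there exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tracer import LabelingEnvironment

__all__ = [
    "RoiMeasurement",
    "CellGeometry",
    "CellRates",
    "SymbiosisRate",
    "MOLAR_MASS_C",
    "roi_atom_fractions",
    "biovolume_pennate",
    "nitrogen_quota",
    "cell_n2_rate",
    "growth_rate_13c",
    "symbiosis_rate",
    "cell_rates_table",
]

MOLAR_MASS_C = 12.011  # g mol-1

#: Carbon-per-volume power law pgC = a * V**b for diatoms.
CARBON_POWERLAW_A = 0.288
CARBON_POWERLAW_B = 0.811
REDFIELD_CN = 6.625


@dataclass(frozen=True)
class RoiMeasurement:
    """Secondary-ion counts of one ROI (one cell) on a nanoSIMS image."""

    symbiosis_id: str
    roi_id: str
    part: str               # "symbiont" or "host"
    c15n: float
    c14n: float
    c13c: float
    c12c: float

    def __post_init__(self) -> None:
        for name in ("c15n", "c14n", "c13c", "c12c"):
            if getattr(self, name) < 0:
                raise ValueError(f"ion count {name} must be >= 0")
        if self.part not in ("symbiont", "host"):
            raise ValueError(f"part must be 'symbiont' or 'host', got {self.part!r}")


@dataclass(frozen=True)
class CellGeometry:
    """Cell dimensions in micrometres; height defaults to width."""

    length_um: float
    width_um: float
    height_um: float | None = None

    def __post_init__(self) -> None:
        h = self.width_um if self.height_um is None else self.height_um
        object.__setattr__(self, "height_um", h)
        for name in ("length_um", "width_um", "height_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class CellRates:
    """Derived per-cell activity."""

    n2fix_fmol_d: float
    growth_d: float
    quota_fmol_n: float
    n_clipped: bool = False  # negative 15N excess clipped to zero rate
    c_clipped: bool = False  # negative 13C excess clipped to zero growth


@dataclass(frozen=True)
class SymbiosisRate:
    """Whole-symbiosis rate: sum over host + symbiont cells."""

    symbiosis_id: str
    n2fix_fmol_d: float
    n_rois: int
    any_clipped: bool


def roi_atom_fractions(roi: RoiMeasurement) -> tuple[float, float]:
    """15N and 13C atom fractions of one ROI from its ion counts."""
    n_total = roi.c15n + roi.c14n
    c_total = roi.c13c + roi.c12c
    if n_total <= 0:
        raise ValueError(f"ROI {roi.roi_id}: zero total N ion counts")
    if c_total <= 0:
        raise ValueError(f"ROI {roi.roi_id}: zero total C ion counts")
    return roi.c15n / n_total, roi.c13c / c_total


def biovolume_pennate(g: CellGeometry) -> float:
    """Elliptic-prism biovolume of a pennate cell, um^3."""
    return math.pi / 4.0 * g.length_um * g.width_um * g.height_um


def nitrogen_quota(
    v_um3: float,
    cn_ratio: float = REDFIELD_CN,
    a: float = CARBON_POWERLAW_A,
    b: float = CARBON_POWERLAW_B,
) -> float:
    """Cellular nitrogen quota (fmol N) from biovolume.

    pgC = a * V**b; quota = pgC / 12.011 / cn_ratio * 1000 fmol N.
    """
    if not v_um3 > 0:
        raise ValueError(f"biovolume must be > 0, got {v_um3}")
    if not cn_ratio > 0:
        raise ValueError(f"C:N ratio must be > 0, got {cn_ratio}")
    pg_c = a * v_um3**b
    return pg_c / MOLAR_MASS_C / cn_ratio * 1000.0


def cell_n2_rate(
    a_n: float, quota_fmol_n: float, env: LabelingEnvironment
) -> tuple[float, bool]:
    """Per-cell N2-fixation rate, fmol N cell-1 d-1.

    Returns ``(rate, clipped)``: a negative 15N excess is clipped to zero
    at the rate stage only (the raw atom fraction is untouched) and flagged.
    """
    if not quota_fmol_n > 0:
        raise ValueError(f"nitrogen quota must be > 0, got {quota_fmol_n}")
    if env.a_n2 <= env.a_nat_n:
        raise ValueError("degenerate labeling: a_N2 must exceed a_nat_N")
    ex = a_n - env.a_nat_n
    if ex < 0:
        return 0.0, True
    return ex / (env.a_n2 - env.a_nat_n) * quota_fmol_n / env.t_days, False


def growth_rate_13c(a_c: float, env: LabelingEnvironment) -> tuple[float, bool]:
    """13C-based specific growth rate, d-1, as ``(mu, clipped)``.

    mu = -(1/t) ln(1 - E/S). Negative excess is clipped to zero growth and
    flagged; enrichment at or above the DIC source (E >= S) is impossible
    under the exponential-labelling model and raises.
    """
    if not 0.0 <= a_c <= 1.0:
        raise ValueError(f"aC must be an atom fraction in [0,1], got {a_c}")
    e = a_c - env.a_nat_c
    s = env.a_dic - env.a_nat_c
    if e <= 0:
        return 0.0, e < 0
    if e >= s:
        raise ValueError(
            f"13C enrichment (E={e:.6g}) at or above the DIC source (S={s:.6g}) "
            "is impossible under exponential labelling"
        )
    return -math.log(1.0 - e / s) / env.t_days, False


def symbiosis_rate(
    rois: Iterable[RoiMeasurement],
    quotas_fmol_n: Mapping[str, float],
    env: LabelingEnvironment,
) -> SymbiosisRate:
    """Whole-symbiosis N2-fixation rate: sum of all part ROIs.

    ``quotas_fmol_n`` maps each part present among the ROIs ("symbiont",
    "host") to its per-cell nitrogen quota. Host enrichment is included so
    fixed N transferred to the host is counted once; restrict ``rois`` to
    symbiont ROIs to get a symbiont-only rate.
    """
    rois = list(rois)
    if not any(r.part == "symbiont" for r in rois):
        raise ValueError("symbiosis_rate requires at least one symbiont ROI")
    ids = {r.symbiosis_id for r in rois}
    if len(ids) != 1:
        raise ValueError(f"ROIs span multiple symbioses: {sorted(ids)}")
    missing = {r.part for r in rois} - set(quotas_fmol_n)
    if missing:
        raise ValueError(f"missing nitrogen quota for part(s): {sorted(missing)}")

    total = 0.0
    clipped = False
    for roi in rois:
        a_n, _ = roi_atom_fractions(roi)
        rate, clip = cell_n2_rate(a_n, quotas_fmol_n[roi.part], env)
        total += rate
        clipped |= clip
    return SymbiosisRate(ids.pop(), total, len(rois), clipped)


def cell_rates_table(
    roi_df: pd.DataFrame,
    geometry_df: pd.DataFrame,
    env: LabelingEnvironment,
    cn_ratio: float = REDFIELD_CN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI rates and per-symbiosis totals from tidy input tables.

    ``roi_df`` columns: symbiosis_id, roi_id, part, c15N, c14N, c13C, c12C.
    ``geometry_df`` columns: symbiosis_id, part, length_um, width_um
    [, height_um]. Returns ``(per_roi, per_symbiosis)`` frames.
    """
    roi_cols = {c.lower(): c for c in roi_df.columns}
    geo_cols = {c.lower(): c for c in geometry_df.columns}

    quotas: dict[tuple[str, str], float] = {}
    for _, row in geometry_df.iterrows():
        h = row[geo_cols["height_um"]] if "height_um" in geo_cols else None
        if h is not None and (pd.isna(h)):
            h = None
        g = CellGeometry(
            float(row[geo_cols["length_um"]]),
            float(row[geo_cols["width_um"]]),
            None if h is None else float(h),
        )
        key = (str(row[geo_cols["symbiosis_id"]]), str(row[geo_cols["part"]]))
        quotas[key] = nitrogen_quota(biovolume_pennate(g), cn_ratio)

    per_roi_rows = []
    for _, row in roi_df.iterrows():
        roi = RoiMeasurement(
            symbiosis_id=str(row[roi_cols["symbiosis_id"]]),
            roi_id=str(row[roi_cols["roi_id"]]),
            part=str(row[roi_cols["part"]]),
            c15n=float(row[roi_cols["c15n"]]),
            c14n=float(row[roi_cols["c14n"]]),
            c13c=float(row[roi_cols["c13c"]]),
            c12c=float(row[roi_cols["c12c"]]),
        )
        key = (roi.symbiosis_id, roi.part)
        if key not in quotas:
            raise ValueError(f"no geometry/quota for symbiosis {key[0]!r} part {key[1]!r}")
        a_n, a_c = roi_atom_fractions(roi)
        quota = quotas[key]
        rate, n_clip = cell_n2_rate(a_n, quota, env)
        mu, c_clip = growth_rate_13c(a_c, env)
        per_roi_rows.append(
            {
                "symbiosis_id": roi.symbiosis_id,
                "roi_id": roi.roi_id,
                "part": roi.part,
                "aN": a_n,
                "aC": a_c,
                "quota_fmolN": quota,
                "n2fix_fmol_d": rate,
                "growth_d": mu,
                "n_clipped": n_clip,
                "c_clipped": c_clip,
            }
        )
    per_roi = pd.DataFrame(per_roi_rows)

    per_sym = (
        per_roi.groupby("symbiosis_id", sort=True)
        .agg(
            n2fix_fmol_d=("n2fix_fmol_d", "sum"),
            n_rois=("roi_id", "count"),
            any_clipped=("n_clipped", "any"),
        )
        .reset_index()
    )
    return per_roi, per_sym
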