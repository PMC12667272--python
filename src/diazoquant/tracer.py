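"""Isotope bookkeeping shared by every rate calculation.

All enrichment values are carried internally as *atom fractions* in [0, 1]
(the proportion of an element's atoms that are the heavy isotope). Atom
percent (atom%) is accepted only at I/O boundaries via
:func:`percent_to_fraction`; keeping a single canonical unit prevents silent
100-fold errors when values flow between the bulk, single-cell and
contribution stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "NATURAL_15N",
    "NATURAL_13C",
    "LabelingEnvironment",
    "atom_fraction_from_ratio",
    "ratio_from_atom_fraction",
    "excess",
    "percent_to_fraction",
    "fraction_to_percent",
]

#: Natural abundance of 15N (atom fraction, atmospheric N2 standard).
NATURAL_15N = 0.0036765
#: Natural abundance of 13C (atom fraction, VPDB-derived).
NATURAL_13C = 0.0111


def _check_fraction(value: float, name: str) -> float:
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ValueError(f"{name} must be a finite number, got {value!r}")
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be an atom fraction in [0, 1], got {value}")
    return float(value)


def atom_fraction_from_ratio(r: float) -> float:
    """Convert a heavy/light isotope ratio R to an atom fraction R/(1+R).

    Strictly increasing in R; the result is always < 1 for finite R.
    """
    if not (isinstance(r, (int, float)) and math.isfinite(r)):
        raise ValueError(f"isotope ratio must be finite, got {r!r}")
    if r < 0:
        raise ValueError(f"isotope ratio must be >= 0, got {r}")
    return r / (1.0 + r)


def ratio_from_atom_fraction(a: float) -> float:
    """Inverse of :func:`atom_fraction_from_ratio`: a/(1-a)."""
    _check_fraction(a, "atom fraction")
    if a == 1.0:
        raise ValueError("atom fraction 1.0 corresponds to an infinite ratio")
    return a / (1.0 - a)


def excess(a: float, a_ref: float) -> float:
    """Signed enrichment of ``a`` above a reference atom fraction.

    The sign is preserved: values below the reference come back negative.
    Whether to clip a negative excess is a caller decision (the rate
    functions clip and flag; raw atom fractions are never altered).
    """
    _check_fraction(a, "a")
    _check_fraction(a_ref, "a_ref")
    return a - a_ref


def percent_to_fraction(a_pct: float) -> float:
    """Convert atom% (0-100) to an atom fraction (0-1)."""
    if not (isinstance(a_pct, (int, float)) and math.isfinite(a_pct)):
        raise ValueError(f"atom%% must be finite, got {a_pct!r}")
    if not 0.0 <= a_pct <= 100.0:
        raise ValueError(f"atom%% must be in [0, 100], got {a_pct}")
    return a_pct / 100.0


def fraction_to_percent(a: float) -> float:
    """Convert an atom fraction (0-1) to atom% (0-100)."""
    return _check_fraction(a, "atom fraction") * 100.0


@dataclass(frozen=True)
class LabelingEnvironment:
    """Isotopic composition of the source pools during an incubation.

    Parameters
    ----------
    a_n2 : float
        Atom fraction 15N of the dissolved N2 pool after tracer addition.
        Not a literature constant: it depends on how much labelled gas
        dissolved, so it must be supplied per experiment (measured, e.g. by
        membrane-inlet mass spectrometry, or computed from the added tracer
        volume and N2 solubility).
    a_dic : float
        Atom fraction 13C of dissolved inorganic carbon after tracer
        addition.
    t_days : float
        Incubation duration in days (sub-daily incubations are fractional).
    a_nat_n, a_nat_c : float
        Natural-abundance references, overridable for non-default standards.
    """

    a_n2: float
    a_dic: float
    t_days: float
    a_nat_n: float = NATURAL_15N
    a_nat_c: float = NATURAL_13C

    def __post_init__(self) -> None:
        _check_fraction(self.a_n2, "a_n2")
        _check_fraction(self.a_dic, "a_dic")
        _check_fraction(self.a_nat_n, "a_nat_n")
        _check_fraction(self.a_nat_c, "a_nat_c")
        if not 0.0 < self.a_nat_n < self.a_n2:
            raise ValueError(
                f"require 0 < a_nat_n < a_n2, got a_nat_n={self.a_nat_n}, a_n2={self.a_n2}"
            )
        if not 0.0 < self.a_nat_c < self.a_dic:
            raise ValueError(
                f"require 0 < a_nat_c < a_dic, got a_nat_c={self.a_nat_c}, a_dic={self.a_dic}"
            )
        if not (math.isfinite(self.t_days) and self.t_days > 0):
            raise ValueError(f"incubation duration must be > 0 days, got {self.t_days}")

    @classmethod
    def from_config(cls, labeling: Mapping[str, float]) -> "LabelingEnvironment":
        """Build from a config ``labeling:`` block.

        Keys: a_N2, a_DIC, t_days and optional a_nat_N, a_nat_C. Any
        enrichment key may instead carry the suffix ``_pct`` to supply the
        value in atom% (e.g. ``a_N2_pct: 2.5``).
        """
        def pick(base: str, default: float | None = None) -> float:
            lower = {k.lower(): v for k, v in labeling.items()}
            if f"{base}_pct".lower() in lower:
                return percent_to_fraction(float(lower[f"{base}_pct".lower()]))
            if base.lower() in lower:
                return float(lower[base.lower()])
            if default is not None:
                return default
            raise KeyError(f"labeling config missing required key {base!r}")

        return cls(
            a_n2=pick("a_N2"),
            a_dic=pick("a_DIC"),
            t_days=float(labeling.get("t_days", labeling.get("t", 0.0)) or pick("t_days")),
            a_nat_n=pick("a_nat_N", NATURAL_15N),
            a_nat_c=pick("a_nat_C", NATURAL_13C),
        )
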