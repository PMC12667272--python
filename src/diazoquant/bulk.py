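"""Volumetric N2-fixation rates from 15N incorporation into particulate N.

The bulk rate follows the standard tracer mass balance: the fraction of the
particulate-nitrogen pool that was newly fixed over the incubation is the
rise of its 15N atom fraction divided by the labelling of the N2 source
pool, and the volumetric rate is that fraction times the PN concentration
divided by the incubation time:

    rate = (a_PNt - a_PN0) / (a_N2 - a_PN0) * PN / t        [nmol N L-1 d-1]

A minimum quantifiable rate (MQR) per sample propagates the smallest
resolvable enrichment, k * sigma_a, through the same equation; a station/
depth group is flagged ``detected`` only when its replicate-mean rate
reaches the group MQR. Negative rates (a_PNt below a_PN0) are reported and
flagged, never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tracer import LabelingEnvironment

__all__ = [
    "IncubationSample",
    "RateResult",
    "bulk_rate",
    "replicate_stats",
    "minimum_quantifiable_rate",
    "rate_table",
]


@dataclass(frozen=True)
class IncubationSample:
    """One replicate bottle of a 15N2 tracer incubation."""

    station: str
    depth_m: float
    replicate: int
    pn_nmol_l: float        # particulate N concentration, nmol N L-1
    a_pn0: float            # atom fraction 15N of PN at t0
    a_pnt: float            # atom fraction 15N of PN at t_end
    env: LabelingEnvironment

    def __post_init__(self) -> None:
        if not self.pn_nmol_l > 0:
            raise ValueError(f"PN concentration must be > 0, got {self.pn_nmol_l}")
        for name in ("a_pn0", "a_pnt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be an atom fraction in [0,1], got {v}")
        if self.a_pn0 >= self.env.a_n2:
            raise ValueError(
                "degenerate labeling: initial PN atom fraction "
                f"({self.a_pn0}) must lie below the N2 pool enrichment ({self.env.a_n2})"
            )


@dataclass(frozen=True)
class RateResult:
    """Replicate-aggregated volumetric rate with its detection decision."""

    station: str
    depth_m: float
    rate_mean: float        # nmol N L-1 d-1
    rate_sd: float          # nan when n == 1
    n: int
    mqr: float              # minimum quantifiable rate, same units
    detected: bool


def bulk_rate(s: IncubationSample) -> float:
    """Volumetric N2-fixation rate of one replicate, nmol N L-1 d-1.

    Negative enrichment gives a negative rate; callers decide how to flag
    it (see :func:`rate_table`).
    """
    return (s.a_pnt - s.a_pn0) / (s.env.a_n2 - s.a_pn0) * s.pn_nmol_l / s.env.t_days


def replicate_stats(rates: Sequence[float]) -> tuple[float, float, int]:
    """Mean, sample (n-1) SD and count of replicate rates.

    With a single replicate the SD is undefined and returned as NaN.
    """
    rates = [float(r) for r in rates]
    if len(rates) == 0:
        raise ValueError("replicate_stats requires at least one rate")
    n = len(rates)
    mean = float(np.mean(rates))
    sd = float(np.std(rates, ddof=1)) if n > 1 else float("nan")
    return mean, sd, n


def minimum_quantifiable_rate(
    s: IncubationSample, sigma_a: float, k: float = 3.0
) -> float:
    """Smallest quantifiable rate given the atom-fraction measurement noise.

    Propagates the minimum resolvable enrichment k*sigma_a through the rate
    equation: mqr = k*sigma_a / (a_N2 - a_PN0) * PN / t. Monotone
    increasing in both sigma_a and the coverage factor k.
    """
    if not sigma_a >= 0:
        raise ValueError(f"sigma_a must be >= 0, got {sigma_a}")
    if not k > 0:
        raise ValueError(f"coverage factor k must be > 0, got {k}")
    return k * sigma_a / (s.env.a_n2 - s.a_pn0) * s.pn_nmol_l / s.env.t_days


def rate_table(
    samples: Iterable[IncubationSample], sigma_a: float, k: float = 3.0
) -> pd.DataFrame:
    """Aggregate replicates into one row per station x depth.

    Columns mirror :class:`RateResult` plus a ``negative`` audit flag.
    The group MQR is the mean of the replicate-level MQRs; ``detected`` is
    ``rate_mean >= mqr``. Non-detected and negative means are retained for
    audit, never dropped or zeroed.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("rate_table requires at least one sample")

    rows = []
    groups: dict[tuple[str, float], list[IncubationSample]] = {}
    for s in samples:
        groups.setdefault((s.station, s.depth_m), []).append(s)

    for (station, depth), members in groups.items():
        envs = {m.env for m in members}
        if len(envs) > 1:
            raise ValueError(
                f"inconsistent labeling environment across replicates of "
                f"station {station!r} depth {depth}"
            )
        rates = [bulk_rate(m) for m in members]
        mean, sd, n = replicate_stats(rates)
        mqr = float(np.mean([minimum_quantifiable_rate(m, sigma_a, k) for m in members]))
        rows.append(
            {
                "station": station,
                "depth_m": depth,
                "rate_mean": mean,
                "rate_sd": sd,
                "n": n,
                "mqr": mqr,
                "detected": bool(mean >= mqr),
                "negative": bool(mean < 0),
            }
        )
    return pd.DataFrame(rows)


def read_incubations(path, env: LabelingEnvironment) -> list[IncubationSample]:
    """Read an incubation TSV into samples.

    Expected columns: station, depth_m, replicate, PN_nmol_L, aPN0, aPNt.
    The two atom-fraction columns may instead be given in atom% as
    aPN0_pct / aPNt_pct.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}

    def frac(row, base: str) -> float:
        if f"{base}_pct".lower() in cols:
            return float(row[cols[f"{base}_pct".lower()]]) / 100.0
        return float(row[cols[base.lower()]])

    samples = []
    for _, row in df.iterrows():
        samples.append(
            IncubationSample(
                station=str(row[cols["station"]]),
                depth_m=float(row[cols["depth_m"]]),
                replicate=int(row[cols["replicate"]]),
                pn_nmol_l=float(row[cols["pn_nmol_l"]]),
                a_pn0=frac(row, "aPN0"),
                a_pnt=frac(row, "aPNt"),
                env=env,
            )
        )
    return samples
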