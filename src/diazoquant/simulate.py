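"""Synthetic mock-cruise data with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without any archived cruise
data: this module plants known truths and emits the same TSV/FASTA dialects
the analysis modules read.

* Tracer incubations: triplicate bottles per station x depth whose final
  PN atom fraction is the exact inversion of the bulk-rate equation for a
  planted true rate, plus Gaussian measurement noise on the atom fraction.
* nanoSIMS ROIs: per-symbiosis target atom fractions obtained by inverting
  the single-cell rate and growth equations for planted values, then ion
  counts drawn as Poisson splits of a per-ROI ion budget.
* nifH ASV dataset: clade seed sequences kept apart by rejection sampling
  at a minimum between-clade divergence, members mutated at half the
  target within-clade pairwise divergence, and counts drawn sample-wise
  from a Dirichlet-multinomial.

Defaults mirror the study conditions: three gyre stations with bulk rates
0.58/0.32/0.43 nmol N L-1 d-1, triplicates over ~24 h, four measured
symbioses with planted rates {186, 747, 747, 2552} fmol N symb-1 d-1
(mean exactly 1058) and growth 0.5 d-1, microscopy abundances near
107-160 symbioses L-1 at 19-31 ml equivalent filter volumes, and 325-bp
amplicons. A single root seed fans out to per-generator child streams via
``numpy.random.SeedSequence.spawn``, so each table can be regenerated
independently.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .clades import write_fasta
from .singlecell import biovolume_pennate, CellGeometry, nitrogen_quota
from .tracer import LabelingEnvironment

__all__ = [
    "CladePlan",
    "SimConfig",
    "default_environment",
    "preset",
    "gen_incubations",
    "gen_rois",
    "gen_asv_dataset",
    "gen_survey",
]

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_environment() -> LabelingEnvironment:
    """Labelling conditions used by all presets: a_N2=0.025, a_DIC=0.05, t=1 d."""
    return LabelingEnvironment(a_n2=0.025, a_dic=0.05, t_days=1.0)


@dataclass(frozen=True)
class CladePlan:
    """Shape of the planted amplicon clade structure."""

    n_clades: int = 5
    members_per_clade: int = 4
    within_divergence: float = 0.02   # expected member-member pairwise divergence
    between_divergence: float = 0.12  # minimum seed-seed divergence
    seq_length: int = 325
    include_singleton: bool = True    # plant one dataset-wide singleton ASV

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_divergence < self.between_divergence <= 1.0:
            raise ValueError(
                "require 0 <= within_divergence < between_divergence <= 1, got "
                f"{self.within_divergence} / {self.between_divergence}"
            )
        if self.n_clades < 1 or self.members_per_clade < 1 or self.seq_length < 1:
            raise ValueError("clade plan sizes must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Planted truths and noise levels of a mock cruise."""

    seed: int = 0
    # station -> (depth_m, true bulk rate nmol N L-1 d-1)
    true_bulk_rates: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "SO245-2": (62.0, 0.58),
            "SO245-8": (21.0, 0.32),
            "SO245-10": (27.0, 0.43),
        }
    )
    pn_nmol_l: float = 500.0
    noise_sd_atomfrac: float = 2e-6
    n_replicates: int = 3
    # microscopy: station -> (count, equivalent volume L)
    filter_counts: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "SO245-2": (3, 0.0234),
            "SO245-8": (3, 0.028),
            "SO245-10": (4, 0.025),
        }
    )
    # nanoSIMS: planted whole-symbiosis rates, fmol N symb-1 d-1
    planted_cell_rates: tuple[float, ...] = (186.0, 747.0, 747.0, 2552.0)
    planted_growth_d: float = 0.5
    symbionts_per_host: int = 2
    roi_ion_budget: float = 1e6
    symbiont_enrich_ratio: float = 0.4  # symbiont 15N excess as fraction of source excess
    host_enrich_ratio: float = 0.5      # host target excess ratio, sets host geometry
    clade_plan: CladePlan = field(default_factory=CladePlan)
    n_samples: int = 12
    read_depth: int = 20000
    dirichlet_alpha: float = 50.0
    marine1_weight: float = 0.92        # planted Marine-1 share of gyre reads


def preset(name: str, seed: int = 0) -> SimConfig:
    """Named study-condition presets: ``default``, ``null``, ``highnoise``."""
    base = SimConfig(seed=seed)
    if name == "default":
        return base
    if name == "null":
        return replace(
            base,
            true_bulk_rates={s: (d, 0.0) for s, (d, _) in base.true_bulk_rates.items()},
            filter_counts={s: (0, v) for s, (_, v) in base.filter_counts.items()},
            planted_cell_rates=(0.0,) * 4,
            planted_growth_d=0.0,
            marine1_weight=0.0,
        )
    if name == "highnoise":
        return replace(base, noise_sd_atomfrac=base.noise_sd_atomfrac * 10.0)
    raise ValueError(f"unknown preset {name!r}; choose default, null or highnoise")


def _streams(cfg: SimConfig) -> dict[str, np.random.Generator]:
    """Fan the root seed out to one independent child stream per generator."""
    root = np.random.SeedSequence(cfg.seed)
    names = ("incubations", "rois", "asv")
    return {n: np.random.Generator(np.random.PCG64(s)) for n, s in zip(names, root.spawn(len(names)))}


# ---------------------------------------------------------------------------
# Tracer incubations


def gen_incubations(
    cfg: SimConfig, env: LabelingEnvironment, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triplicate incubation table plus the planted-truth table.

    For true rate r*, the noiseless final atom fraction is the exact
    inversion of the bulk-rate equation,
    a_PNt = a_PN0 + r* t (a_N2 - a_PN0) / PN, to which Gaussian noise of
    sd ``noise_sd_atomfrac`` is added. Draws that leave [0, 1] are
    resampled; the truth table reports how many resamples occurred.
    """
    rng = _streams(cfg)["incubations"] if rng is None else rng
    a0 = env.a_nat_n
    rows, truth = [], []
    for station, (depth, r_true) in cfg.true_bulk_rates.items():
        target = a0 + r_true * env.t_days * (env.a_n2 - a0) / cfg.pn_nmol_l
        resampled = 0
        for rep in range(1, cfg.n_replicates + 1):
            a_pnt = target + rng.normal(0.0, cfg.noise_sd_atomfrac)
            while not 0.0 <= a_pnt <= 1.0:
                resampled += 1
                a_pnt = target + rng.normal(0.0, cfg.noise_sd_atomfrac)
            rows.append(
                {
                    "station": station,
                    "depth_m": depth,
                    "replicate": rep,
                    "PN_nmol_L": cfg.pn_nmol_l,
                    "aPN0": a0,
                    "aPNt": a_pnt,
                }
            )
        truth.append(
            {
                "station": station,
                "depth_m": depth,
                "true_rate": r_true,
                "resampled": resampled,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# nanoSIMS ROIs


_BASE_HOST = CellGeometry(36.9, 5.0)     # study-mean host, scaled per planted rate
_SYMBIONT_GEOM = CellGeometry(2.4, 1.2)  # intracellular rhizobial symbiont


def _host_geometry(host_rate: float, env: LabelingEnvironment, ratio: float) -> CellGeometry:
    """Host size whose quota puts the planted host rate at a target excess ratio.

    Scaling all three dimensions by s multiplies the quota by s**(3*0.811);
    we solve for the s that makes rate = ratio * quota / t.
    """
    base_quota = nitrogen_quota(biovolume_pennate(_BASE_HOST))
    needed = host_rate * env.t_days / ratio
    s = (needed / base_quota) ** (1.0 / (3 * 0.811))
    return CellGeometry(_BASE_HOST.length_um * s, _BASE_HOST.width_um * s)


def gen_rois(
    cfg: SimConfig, env: LabelingEnvironment, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ROI ion-count and geometry tables with a per-symbiosis truth table.

    Each planted whole-symbiosis rate is split between ``symbionts_per_host``
    symbiont cells — pinned at ``symbiont_enrich_ratio`` of the source
    excess, emulating rapid transfer of fixed N to the host — and the host,
    which receives the remainder. Host geometry is scaled so its planted
    rate sits at ``host_enrich_ratio`` of the source excess (the paper's
    morphologically distinct large host motivates size varying with
    activity). Target atom fractions invert the rate equations exactly;
    ion counts are Poisson draws splitting ``roi_ion_budget`` between the
    isotopologues (half the budget to N ions, half to C).

    A planted rate whose implied enrichment would reach the source
    labelling is rejected at generation.
    """
    rng = _streams(cfg)["rois"] if rng is None else rng
    stations = list(cfg.true_bulk_rates)
    sym_quota = nitrogen_quota(biovolume_pennate(_SYMBIONT_GEOM))
    source_excess = env.a_n2 - env.a_nat_n

    roi_rows, geom_rows, truth = [], [], []
    for idx, total_rate in enumerate(cfg.planted_cell_rates, start=1):
        sid = f"sym_{idx:02d}"
        station = stations[(idx - 1) % len(stations)]
        k = cfg.symbionts_per_host
        if total_rate > 0:
            sym_rate = cfg.symbiont_enrich_ratio * sym_quota / env.t_days
            sym_rate = min(sym_rate, total_rate / (k + 1))  # tiny planted totals
            host_rate = total_rate - k * sym_rate
            host_geom = _host_geometry(host_rate, env, cfg.host_enrich_ratio)
        else:
            sym_rate, host_rate = 0.0, 0.0
            host_geom = _BASE_HOST
        host_quota = nitrogen_quota(biovolume_pennate(host_geom))

        parts = [("host", "roi_host", host_rate, host_quota)] + [
            (f"symbiont", f"roi_sym{j}", sym_rate, sym_quota) for j in range(1, k + 1)
        ]
        mu = cfg.planted_growth_d
        s_c = env.a_dic - env.a_nat_c
        a_c = env.a_nat_c + s_c * (1.0 - math.exp(-mu * env.t_days))
        for part, roi_id, rate, quota in parts:
            a_n = env.a_nat_n + rate * env.t_days * source_excess / quota
            if a_n >= env.a_n2:
                raise ValueError(
                    f"planted rate {rate} fmol/d for {sid}/{part} exceeds the "
                    f"quota-feasible enrichment (aN={a_n:.4f} >= a_N2={env.a_n2})"
                )
            n_budget = c_budget = cfg.roi_ion_budget / 2.0
            roi_rows.append(
                {
                    "symbiosis_id": sid,
                    "roi_id": f"{sid}_{roi_id}",
                    "part": part,
                    "c15N": int(rng.poisson(n_budget * a_n)),
                    "c14N": int(rng.poisson(n_budget * (1.0 - a_n))),
                    "c13C": int(rng.poisson(c_budget * a_c)),
                    "c12C": int(rng.poisson(c_budget * (1.0 - a_c))),
                }
            )
        geom_rows.append(
            {
                "symbiosis_id": sid,
                "part": "host",
                "length_um": host_geom.length_um,
                "width_um": host_geom.width_um,
                "height_um": host_geom.height_um,
            }
        )
        geom_rows.append(
            {
                "symbiosis_id": sid,
                "part": "symbiont",
                "length_um": _SYMBIONT_GEOM.length_um,
                "width_um": _SYMBIONT_GEOM.width_um,
                "height_um": _SYMBIONT_GEOM.height_um,
            }
        )
        truth.append(
            {
                "symbiosis_id": sid,
                "station": station,
                "true_total_fmol_d": total_rate,
                "true_host_fmol_d": host_rate,
                "true_symbiont_fmol_d": sym_rate,
                "true_growth_d": mu,
            }
        )
    return pd.DataFrame(roi_rows), pd.DataFrame(geom_rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# nifH amplicon dataset


def _mutate(
    seq: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    exact: bool = False,
) -> np.ndarray:
    """Substitute positions of ``seq`` to different bases.

    ``exact=True`` plants exactly round(L * rate) substitutions (used for
    clade members, so the maximum within-clade pairwise divergence is
    bounded by construction); otherwise the count is Binomial(L, rate).
    """
    n_mut = round(len(seq) * rate) if exact else rng.binomial(len(seq), rate)
    if n_mut == 0:
        return seq.copy()
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = seq.copy()
    for p in pos:
        choices = _NT[_NT != out[p]]
        out[p] = rng.choice(choices)
    return out


def _seed_sequences(plan: CladePlan, rng: np.random.Generator) -> list[np.ndarray]:
    """Clade seeds pairwise separated by >= between_divergence (rejection).

    Seeds are homologous variants of one common ancestor (each mutated at
    0.6 x between_divergence, putting the expected pairwise seed
    divergence just above the target) rather than independent random
    sequences: clades of a marker gene share most of their sequence, and
    independent draws would be ~75% divergent.
    """
    ancestor = rng.choice(_NT, size=plan.seq_length)
    seeds: list[np.ndarray] = []
    min_diff = math.ceil(plan.between_divergence * plan.seq_length)
    attempts = 0
    while len(seeds) < plan.n_clades:
        cand = _mutate(ancestor, 0.6 * plan.between_divergence, rng)
        if all(int((cand != s).sum()) >= min_diff for s in seeds):
            seeds.append(cand)
        attempts += 1
        if attempts > 1000 * plan.n_clades:
            raise RuntimeError(
                f"could not separate {plan.n_clades} clade seeds by "
                f">={plan.between_divergence} divergence after {attempts} attempts"
            )
    return seeds


def gen_asv_dataset(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], pd.DataFrame, dict]:
    """FASTA dict, samples x ASVs count table, and the truth clade structure.

    Members of a clade each carry exactly round(within_divergence/2 x L)
    substitutions at random positions, so the member-to-member pairwise
    divergence never exceeds within_divergence (substitutions only, keeping
    gap handling a separately tested concern). With
    within_divergence < 1 - theta < between-clade member divergence, clade
    recovery at theta is guaranteed by construction.
    Counts come from a Dirichlet-multinomial: per-sample clade proportions
    drawn from Dirichlet(alpha * base weights), then split evenly among the
    clade's member ASVs. The first ceil(n_clades/2) clades are planted as
    the "Marine 1"-like group and receive ``marine1_weight`` of the base
    weight in every sample. Optionally one extra dataset-wide singleton ASV
    is planted (one read in the first sample) as filter-rule fodder.
    """
    rng = _streams(cfg)["asv"] if rng is None else rng
    plan = cfg.clade_plan
    seeds = _seed_sequences(plan, rng)

    seqs: dict[str, str] = {}
    clade_of: dict[str, str] = {}
    asv_ids: list[str] = []
    n_m1 = max(1, math.ceil(plan.n_clades / 2)) if cfg.marine1_weight > 0 else 0
    marine1 = []
    for c, seed in enumerate(seeds, start=1):
        clade = f"planted_{c:02d}"
        if c <= n_m1:
            marine1.append(clade)
        for m in range(1, plan.members_per_clade + 1):
            asv = f"ASV_{len(asv_ids) + 1:03d}"
            member = _mutate(seed, plan.within_divergence / 2.0, rng, exact=True)
            seqs[asv] = member.tobytes().decode("ascii")
            clade_of[asv] = clade
            asv_ids.append(asv)

    # Dirichlet-multinomial counts
    base = np.ones(plan.n_clades)
    if n_m1:
        base[:n_m1] = cfg.marine1_weight / n_m1
        base[n_m1:] = (1.0 - cfg.marine1_weight) / (plan.n_clades - n_m1 or 1)
    else:
        base /= plan.n_clades
    alpha = np.maximum(cfg.dirichlet_alpha * base, 1e-3)
    counts = np.zeros((cfg.n_samples, len(asv_ids)), dtype=np.int64)
    for i in range(cfg.n_samples):
        p_clade = rng.dirichlet(alpha)
        p_asv = np.repeat(p_clade / plan.members_per_clade, plan.members_per_clade)
        counts[i] = rng.multinomial(cfg.read_depth, p_asv)
    sample_ids = [f"sample_{i + 1:02d}" for i in range(cfg.n_samples)]
    table = pd.DataFrame(counts, index=sample_ids, columns=asv_ids)

    if plan.include_singleton:
        singleton = "ASV_singleton"
        seqs[singleton] = rng.choice(_NT, size=plan.seq_length).tobytes().decode("ascii")
        table[singleton] = 0
        table.loc[sample_ids[0], singleton] = 1
        clade_of[singleton] = "planted_singleton"

    truth = {
        "clade_of": clade_of,
        "marine1_clades": marine1,
        "marine1_weight": cfg.marine1_weight,
        "n_clades": plan.n_clades,
    }
    return seqs, table, truth


# ---------------------------------------------------------------------------
# Full mock cruise


def gen_survey(cfg: SimConfig, out_dir: str | Path) -> Path:
    """Write a full consistent mock-cruise bundle into ``out_dir``.

    Files: incubations.tsv, filter_counts.tsv, rois.tsv, geometry.tsv,
    asv_counts.tsv, asvs.fasta and truth.json (every planted quantity the
    downstream checks need, including per-station contributions and
    percent-of-bulk computed from the planted truths).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    env = default_environment()
    streams = _streams(cfg)

    inc, inc_truth = gen_incubations(cfg, env, streams["incubations"])
    rois, geom, roi_truth = gen_rois(cfg, env, streams["rois"])
    seqs, asv_table, asv_truth = gen_asv_dataset(cfg, streams["asv"])

    counts_rows = [
        {
            "station": station,
            "depth_m": cfg.true_bulk_rates[station][0],
            "count": n,
            "equiv_volume_L": vol,
        }
        for station, (n, vol) in cfg.filter_counts.items()
    ]
    fc = pd.DataFrame(counts_rows)

    def fmt(df: pd.DataFrame, path: Path) -> None:
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")

    fmt(inc, out / "incubations.tsv")
    fmt(fc, out / "filter_counts.tsv")
    fmt(rois, out / "rois.tsv")
    fmt(geom, out / "geometry.tsv")
    asv_table.rename_axis("sample_id").reset_index().to_csv(
        out / "asv_counts.tsv", sep="\t", index=False, lineterminator="\n"
    )
    write_fasta(seqs, out / "asvs.fasta")

    mean_rate = float(np.mean(cfg.planted_cell_rates))
    per_station = {}
    for station, (n, vol) in cfg.filter_counts.items():
        depth, r_true = cfg.true_bulk_rates[station]
        ab = n / vol
        contrib = ab * mean_rate * 1e-6
        per_station[station] = {
            "depth_m": depth,
            "true_bulk_rate": r_true,
            "abundance_per_L": ab,
            "contribution_nmol_L_d": contrib,
            "fraction_pct": 100.0 * contrib / r_true if r_true > 0 else None,
        }
    fractions = [v["fraction_pct"] for v in per_station.values() if v["fraction_pct"]]
    truth = {
        "seed": cfg.seed,
        "labeling": {
            "a_N2": env.a_n2,
            "a_DIC": env.a_dic,
            "t_days": env.t_days,
            "a_nat_N": env.a_nat_n,
            "a_nat_C": env.a_nat_c,
        },
        "bulk": inc_truth.to_dict(orient="records"),
        "symbioses": roi_truth.to_dict(orient="records"),
        "mean_cell_rate_fmol_d": mean_rate,
        "stations": per_station,
        "max_fraction_pct": max(fractions) if fractions else None,
        "amplicon": asv_truth,
        "noise_sd_atomfrac": cfg.noise_sd_atomfrac,
        "pn_nmol_l": cfg.pn_nmol_l,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return out
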