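"""nifH amplicon ASV filtering, pairwise identity, clade clustering and profiles.

Stages, in pipeline order:

1. ``filter_asvs`` removes sequencing bleed-through from a samples x ASVs
   count table: dataset-wide singletons, and ASVs whose total count falls
   below 0.1% of the mean per-sample read depth (applied dataset-wide).
2. ``pairwise_identity`` computes nucleotide identity between two amplicons
   from a global alignment with free terminal gaps (match +1, mismatch -1,
   gap -2): identity = matches / aligned columns, terminal-gap columns
   excluded. ``N`` never counts as a match but its columns stay in the
   denominator.
3. ``cluster_clades`` groups ASVs by agglomerative complete-linkage
   clustering on distance 1 - identity, cut at 1 - theta (theta = 0.95 by
   default). Complete linkage guarantees every clade of size >= 2 has
   minimum within-clade identity >= theta — the property the within-clade
   similarity report then verifies.
4. ``clade_profiles`` turns counts + assignment into per-sample relative
   abundances, with an aggregate fraction for a user-supplied set of clades
   (e.g. the "Marine 1" group of rhizobial diatom-symbiont relatives).

Identity tie-break: among all maximum-score alignments the one with the
most matched columns is used (then the fewest aligned columns). This makes
the reported identity a deterministic, symmetric function of the pair.

With free terminal gaps the optimal alignment of two *unrelated* sequences
degenerates to a short perfect overlap, which would report a spuriously
high identity. Pairs whose optimal alignment covers less than
``MIN_COVERAGE`` of the shorter sequence are therefore reported at
identity 0 (no meaningful homology under this scoring); genuinely related
amplicons of a common trim length are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CladeAssignment",
    "CladeProfile",
    "MATCH",
    "MISMATCH",
    "GAP",
    "filter_asvs",
    "pairwise_identity",
    "alignment_stats",
    "identity_matrix",
    "cluster_clades",
    "within_clade_similarity",
    "clade_profiles",
    "codetection_matrix",
    "read_fasta",
    "write_fasta",
]

MATCH = 1
MISMATCH = -1
GAP = -2
#: Minimum fraction of the shorter sequence the optimal alignment must
#: cover for the identity to be considered meaningful.
MIN_COVERAGE = 0.5

_ALPHABET = set("ACGTN")

# Lexicographic (score, matches, -columns) packed into one int64 per DP cell.
# Ranges: columns <= len_a + len_b, matches <= min(len_a, len_b); the bases
# below are safe for amplicons up to ~50 kb.
_B2 = 1 << 18            # weight of one match
_B1 = 1 << 40            # weight of one score unit


def _validate_seq(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"{name} contains invalid characters {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# ASV table filtering


def filter_asvs(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove bleed-through ASVs from a samples x ASVs count table.

    Removal rules, applied to dataset-wide ASV totals computed on the input
    table:

    - ``singleton``: total count across all samples == 1;
    - ``low_abundance``: total count < 0.001 x mean per-sample depth.

    Returns ``(retained_table, removal_log)`` where the log has one row per
    removed ASV naming the rule that fired (singletons that also fail the
    abundance rule are logged as singletons). Filtering is idempotent: the
    threshold is a fixed function of the input table, and re-filtering the
    retained table removes nothing further only because retained totals
    already exceed max(1, threshold) of the *original* table — which is >=
    the threshold recomputed on the retained table (depths only shrink).
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("ASV table must have at least one sample and one ASV")
    if (counts.values < 0).any():
        raise ValueError("ASV table must be non-negative")

    totals = counts.sum(axis=0)
    mean_depth = counts.sum(axis=1).mean()
    threshold = 0.001 * mean_depth

    log_rows = []
    drop = []
    for asv in counts.columns:
        total = totals[asv]
        if total == 1:
            drop.append(asv)
            log_rows.append({"asv_id": asv, "rule": "singleton", "total_count": int(total)})
        elif total < threshold:
            drop.append(asv)
            log_rows.append(
                {"asv_id": asv, "rule": "low_abundance", "total_count": int(total)}
            )
    retained = counts.drop(columns=drop)
    log = pd.DataFrame(log_rows, columns=["asv_id", "rule", "total_count"])
    return retained, log


# ---------------------------------------------------------------------------
# Pairwise identity


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def alignment_stats(a: str, b: str) -> tuple[int, int, int]:
    """Optimal semi-global alignment of two sequences.

    Returns ``(score, matches, columns)`` for the alignment that maximises
    score, then matches, then minimises aligned columns. Terminal gaps are
    free and excluded from the column count. ``N`` aligned to anything is
    scored as a mismatch and never counts as a match.
    """
    a = _validate_seq(a, "a")
    b = _validate_seq(b, "b")
    xa, xb = _encode(a), _encode(b)
    n, m = len(xa), len(xb)
    ncode = ord("N")

    # Per-edge packed weights: diag = s*B1 + is_match*B2 - 1; gap = -2*B1 - 1.
    gap_w = GAP * _B1 - 1
    jj = np.arange(m + 1, dtype=np.int64)

    prev = np.zeros(m + 1, dtype=np.int64)  # row 0: free leading gaps in b
    best_end = prev[m]                      # alignments ending at column m
    for i in range(n):
        is_match = (xb == xa[i]) & (xb != ncode) & (xa[i] != ncode)
        diag_w = np.where(is_match, MATCH * _B1 + _B2 - 1, MISMATCH * _B1 - 1)
        cand = np.empty(m + 1, dtype=np.int64)
        cand[0] = 0                         # free leading gap in a: start node (i+1, 0)
        cand[1:] = np.maximum(prev[:-1] + diag_w, prev[1:] + gap_w)
        # left-gap chain: cur[j] = max_k<=j cand[k] + gap_w*(j-k)
        cur = np.maximum.accumulate(cand - gap_w * jj) + gap_w * jj
        best_end = max(best_end, cur[m])
        prev = cur
    best = max(best_end, int(prev.max()))   # free trailing gaps on either side

    score, rem = divmod(best, _B1)
    if rem > _B1 // 2:
        score, rem = score + 1, rem - _B1
    matches, neg_cols = divmod(rem, _B2)
    if neg_cols > _B2 // 2:
        matches, neg_cols = matches + 1, neg_cols - _B2
    return int(score), int(matches), int(-neg_cols)


def pairwise_identity(a: str, b: str) -> float:
    """Nucleotide identity of two amplicons in [0, 1].

    matches / aligned columns of the optimal alignment (see
    :func:`alignment_stats`); symmetric in its arguments. Pairs whose
    optimal alignment covers less than ``MIN_COVERAGE`` of the shorter
    sequence (degenerate overlaps between unrelated sequences) report 0.
    """
    _, matches, columns = alignment_stats(a, b)
    if columns < MIN_COVERAGE * min(len(a), len(b)):
        return 0.0
    return matches / columns


def identity_matrix(seqs: Mapping[str, str]) -> pd.DataFrame:
    """Symmetric pairwise identity matrix over a dict of sequences."""
    ids = sorted(seqs)
    k = len(ids)
    mat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = pairwise_identity(seqs[ids[i]], seqs[ids[j]])
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Clade clustering


@dataclass(frozen=True)
class CladeAssignment:
    """Complete-linkage clade membership at identity threshold theta."""

    theta: float
    clade_of: dict[str, str]
    linkage: str = "complete"

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for asv, clade in self.clade_of.items():
            out.setdefault(clade, []).append(asv)
        return {c: sorted(m) for c, m in out.items()}


def cluster_clades(seqs: Mapping[str, str], theta: float = 0.95) -> CladeAssignment:
    """Cluster ASVs into clades by complete linkage on 1 - identity.

    The dendrogram is cut at distance 1 - theta, so every clade of size
    >= 2 is guaranteed a minimum within-clade identity >= theta (asserted
    on the output). Deterministic under input order: sequences are
    processed in lexicographic asv_id order and clades are labelled
    ``clade_01``, ``clade_02``, ... by their smallest member id. Singleton
    clades are permitted (ASVs matching nothing at theta).
    """
    if not seqs:
        raise ValueError("cluster_clades requires at least one sequence")
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    ids = sorted(seqs)
    if len(ids) == 1:
        return CladeAssignment(theta, {ids[0]: "clade_01"})

    ident = identity_matrix(seqs)
    dist = 1.0 - ident.loc[ids, ids].values
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=1.0 - theta, criterion="distance")

    groups: dict[int, list[str]] = {}
    for asv, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(asv)
    ordered = sorted(groups.values(), key=lambda members: members[0])
    width = max(2, len(str(len(ordered))))
    clade_of: dict[str, str] = {}
    for k, members in enumerate(ordered, start=1):
        name = f"clade_{k:0{width}d}"
        for asv in members:
            clade_of[asv] = name

    # complete-linkage guarantee, asserted on every output
    for members in ordered:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if ident.loc[members[i], members[j]] < theta - 1e-12:
                    raise AssertionError(
                        "complete-linkage invariant violated: "
                        f"{members[i]} vs {members[j]} below theta={theta}"
                    )
    return CladeAssignment(theta, clade_of)


def within_clade_similarity(
    assignment: CladeAssignment, seqs: Mapping[str, str]
) -> pd.DataFrame:
    """Per-clade min/max pairwise identity (NaN for singleton clades)."""
    rows = []
    for clade, members in sorted(assignment.members().items()):
        if len(members) < 2:
            rows.append(
                {"clade": clade, "n": 1, "min_identity": np.nan, "max_identity": np.nan}
            )
            continue
        vals = [
            pairwise_identity(seqs[members[i]], seqs[members[j]])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        rows.append(
            {
                "clade": clade,
                "n": len(members),
                "min_identity": min(vals),
                "max_identity": max(vals),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Profiles and co-detection


@dataclass(frozen=True)
class CladeProfile:
    """Per-sample clade composition over retained reads."""

    fractions: pd.DataFrame          # samples x clades, rows sum to 1
    marine1_fraction: pd.Series      # per-sample aggregate over the listed clades
    empty_samples: tuple[str, ...]   # samples with zero retained reads (NaN rows)


def clade_profiles(
    counts: pd.DataFrame,
    assignment: CladeAssignment,
    marine1_clades: Iterable[str] = (),
) -> CladeProfile:
    """Relative clade abundances per sample from a retained count table.

    Every ASV column must be assigned to a clade. Fractions are clade
    read counts over the per-sample retained depth; samples with zero
    retained reads get NaN fractions and are listed in ``empty_samples``.
    """
    missing = [a for a in counts.columns if a not in assignment.clade_of]
    if missing:
        raise ValueError(f"ASVs without clade assignment: {missing}")
    clade_counts = counts.T.groupby(
        counts.columns.map(assignment.clade_of)
    ).sum().T
    depths = clade_counts.sum(axis=1)
    fractions = clade_counts.div(depths.replace(0, np.nan), axis=0)
    empty = tuple(str(s) for s in depths.index[depths == 0])

    marine1 = [c for c in marine1_clades]
    present = [c for c in marine1 if c in fractions.columns]
    marine1_fraction = (
        fractions[present].sum(axis=1, min_count=1)
        if present
        else pd.Series(0.0, index=fractions.index)
    )
    marine1_fraction.name = "marine1_fraction"
    return CladeProfile(fractions, marine1_fraction, empty)


def codetection_matrix(
    seq_presence: Mapping[str, bool],
    qpcr_presence: Mapping[str, bool],
    fish_presence: Mapping[str, bool],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample +/- detection grid across methods plus pairwise agreement.

    All three mappings must cover the same sample set. Returns
    ``(grid, agreement)``: the grid has one boolean column per method; the
    agreement table counts concordant and discordant samples per method
    pair.
    """
    keys = set(seq_presence)
    if set(qpcr_presence) != keys or set(fish_presence) != keys:
        raise ValueError("sample sets differ between detection methods")
    samples = sorted(keys)
    grid = pd.DataFrame(
        {
            "sequencing": [bool(seq_presence[s]) for s in samples],
            "qpcr": [bool(qpcr_presence[s]) for s in samples],
            "fish": [bool(fish_presence[s]) for s in samples],
        },
        index=samples,
    )
    rows = []
    methods = list(grid.columns)
    for i in range(len(methods)):
        for j in range(i + 1, len(methods)):
            agree = int((grid[methods[i]] == grid[methods[j]]).sum())
            rows.append(
                {
                    "method_a": methods[i],
                    "method_b": methods[j],
                    "agree": agree,
                    "disagree": len(samples) - agree,
                }
            )
    return grid, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA I/O (via biopython)


def read_fasta(path) -> dict[str, str]:
    """Read ASV sequences from FASTA into an id -> sequence dict."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = _validate_seq(str(rec.seq), rec.id)
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sorted(seqs.items())]
    seqio_write(records, str(path), "fasta")
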