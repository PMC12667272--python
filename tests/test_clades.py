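import numpy as np
import pandas as pd
import pytest

from diazoquant import (
    clade_profiles,
    cluster_clades,
    codetection_matrix,
    filter_asvs,
    pairwise_identity,
    within_clade_similarity,
)
from diazoquant.clades import MIN_COVERAGE, alignment_stats

from oracles import enumerate_stats, oracle_identity, tuple_dp_stats


def table(data, samples=None):
    samples = samples or [f"s{i}" for i in range(len(next(iter(data.values()))))]
    return pd.DataFrame(data, index=samples)


class TestFilterAsvs:
    def test_singleton_removed(self):
        t = table({"a": [1, 0], "b": [500, 500]})
        retained, log = filter_asvs(t)
        assert list(retained.columns) == ["b"]
        assert log.iloc[0]["rule"] == "singleton"

    def test_low_abundance_threshold_arithmetic(self):
        """Depths {1000, 3000}: threshold 2, so total 1 goes, total 2 stays."""
        t = table({"a": [1, 0], "b": [2, 0], "c": [997, 3000]})
        retained, log = filter_asvs(t)
        assert set(retained.columns) == {"b", "c"}
        assert dict(zip(log["asv_id"], log["rule"])) == {"a": "singleton"}

    def test_low_abundance_rule_attribution(self):
        # total 3 < 0.001 * mean depth (5), not a singleton
        t = table({"a": [3, 0], "b": [4997, 5000]})
        retained, log = filter_asvs(t)
        assert dict(zip(log["asv_id"], log["rule"])) == {"a": "low_abundance"}

    def test_nothing_to_remove(self):
        t = table({"a": [100, 100], "b": [200, 200]})
        retained, log = filter_asvs(t)
        assert retained.equals(t) and len(log) == 0

    def test_idempotent(self):
        t = table({"a": [1, 0], "b": [2, 1], "c": [3000, 2000], "d": [2, 0]})
        once, _ = filter_asvs(t)
        twice, log2 = filter_asvs(once)
        assert once.equals(twice) and len(log2) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            filter_asvs(pd.DataFrame())


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGT" * 81 + "A", "ACGT" * 81 + "A") == 1.0

    def test_single_mismatch(self):
        assert pairwise_identity("ACGT", "ACGA") == 0.75

    def test_internal_deletion(self):
        """One deletion: 7 matches over 8 columns."""
        assert pairwise_identity("ACGTACGT", "ACGACGT") == pytest.approx(7 / 8)

    def test_symmetric(self):
        a, b = "ACGTACGTAC", "ACGTTACGT"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_n_never_matches_but_counts_in_denominator(self):
        assert pairwise_identity("ACGN", "ACGN") == pytest.approx(3 / 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_degenerate_overlap_reports_zero(self):
        """Unrelated sequences must not inherit identity from a tiny overlap."""
        rng = np.random.default_rng(11)
        nt = np.array(list("ACGT"))
        a = "".join(rng.choice(nt, 120))
        b = "".join(rng.choice(nt, 120))
        assert pairwise_identity(a, b) == 0.0

    def test_matches_tuple_dp_oracle_on_random_pairs(self):
        """Packed-integer DP agrees with an independent tuple-valued DP."""
        rng = np.random.default_rng(42)
        alphabet = np.array(list("ACGTN"))
        for _ in range(1000):
            la, lb = rng.integers(1, 9, size=2)
            a = "".join(rng.choice(alphabet, la, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            b = "".join(rng.choice(alphabet, lb, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            assert alignment_stats(a, b) == tuple_dp_stats(a, b), (a, b)
            assert pairwise_identity(a, b) == pytest.approx(oracle_identity(a, b))

    def test_tuple_dp_matches_exhaustive_enumeration(self):
        """The oracle itself is validated against full path enumeration."""
        rng = np.random.default_rng(7)
        alphabet = np.array(list("ACGT"))
        for _ in range(150):
            la, lb = rng.integers(1, 6, size=2)
            a = "".join(rng.choice(alphabet, la))
            b = "".join(rng.choice(alphabet, lb))
            assert tuple_dp_stats(a, b) == enumerate_stats(a, b), (a, b)


def mutated_family(rng, n_clades=3, members=4, length=325, within=0.02, between=0.12):
    """Planted clade structure via the package's own generator."""
    from diazoquant.simulate import CladePlan, SimConfig, gen_asv_dataset

    cfg = SimConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        clade_plan=CladePlan(
            n_clades=n_clades,
            members_per_clade=members,
            within_divergence=within,
            between_divergence=between,
            seq_length=length,
            include_singleton=False,
        ),
    )
    seqs, counts, truth = gen_asv_dataset(cfg)
    return seqs, counts, truth


class TestClusterClades:
    def test_all_similar_single_clade(self):
        seqs = {"a": "ACGT" * 25, "b": "ACGT" * 25, "c": "ACGT" * 24 + "ACGA"}
        ca = cluster_clades(seqs, theta=0.95)
        assert len(set(ca.clade_of.values())) == 1

    def test_chain_never_merges_fully(self):
        """A-B and B-C similar, A-C not: complete linkage refuses {A,B,C}."""
        rng = np.random.default_rng(3)
        nt = np.frombuffer(b"ACGT", dtype=np.uint8)
        base = rng.choice(nt, 100)

        def mutate(seq, positions, revert_to=None):
            out = seq.copy()
            for p in positions:
                out[p] = nt[(np.where(nt == out[p])[0][0] + 1) % 4]
            return out

        a = base
        b = mutate(a, [10, 20, 30, 40])            # A-B identity 0.96
        c = mutate(b, [10, 50, 60, 70])            # B-C 0.96; A-C 0.93
        seqs = {k: v.tobytes().decode() for k, v in {"A": a, "B": b, "C": c}.items()}
        assert pairwise_identity(seqs["A"], seqs["B"]) == pytest.approx(0.96)
        assert pairwise_identity(seqs["B"], seqs["C"]) == pytest.approx(0.96)
        assert pairwise_identity(seqs["A"], seqs["C"]) == pytest.approx(0.93)
        ca = cluster_clades(seqs, theta=0.95)
        sizes = sorted(len(m) for m in ca.members().values())
        assert sizes == [1, 2]  # never one clade of three

    def test_planted_clades_recovered_exactly(self, rng):
        seqs, _, truth = mutated_family(rng)
        ca = cluster_clades(seqs, theta=0.95)
        planted = {}
        for asv, clade in truth["clade_of"].items():
            planted.setdefault(clade, set()).add(asv)
        recovered = {frozenset(m) for m in ca.members().values()}
        assert recovered == {frozenset(m) for m in planted.values()}

    def test_complete_linkage_invariant(self, rng):
        seqs, _, _ = mutated_family(rng, within=0.04)
        ca = cluster_clades(seqs, theta=0.95)
        sim = within_clade_similarity(ca, seqs)
        multi = sim[sim["n"] >= 2]
        assert (multi["min_identity"] >= 0.95).all()

    def test_permutation_invariant_up_to_relabeling(self, rng):
        seqs, _, _ = mutated_family(rng, n_clades=2, members=3, length=120)
        ca1 = cluster_clades(seqs, theta=0.95)
        shuffled = dict(reversed(list(seqs.items())))
        ca2 = cluster_clades(shuffled, theta=0.95)
        parts1 = {frozenset(m) for m in ca1.members().values()}
        parts2 = {frozenset(m) for m in ca2.members().values()}
        assert parts1 == parts2

    def test_singleton_input(self):
        ca = cluster_clades({"only": "ACGT" * 10})
        assert ca.clade_of == {"only": "clade_01"}


class TestWithinCladeSimilarity:
    def test_identical_pair(self):
        ca = cluster_clades({"a": "ACGT" * 20, "b": "ACGT" * 20})
        sim = within_clade_similarity(ca, {"a": "ACGT" * 20, "b": "ACGT" * 20})
        row = sim.iloc[0]
        assert row["min_identity"] == row["max_identity"] == 1.0

    def test_min_max_over_three(self):
        # pairwise identities 0.96 / 0.97 / 0.98 by construction over 100 nt
        rng = np.random.default_rng(5)
        nt = np.frombuffer(b"ACGT", dtype=np.uint8)
        a = rng.choice(nt, 100)
        b = a.copy()
        for p in (0, 1):
            b[p] = nt[(np.where(nt == b[p])[0][0] + 1) % 4]
        c = a.copy()
        for p in (0, 10, 11, 12):
            c[p] = nt[(np.where(nt == c[p])[0][0] + 2) % 4]
        seqs = {k: v.tobytes().decode() for k, v in {"a": a, "b": b, "c": c}.items()}
        ca = cluster_clades(seqs, theta=0.90)
        sim = within_clade_similarity(ca, seqs)
        row = sim[sim["n"] == 3].iloc[0]
        pid = [
            pairwise_identity(seqs[x], seqs[y])
            for x, y in (("a", "b"), ("a", "c"), ("b", "c"))
        ]
        assert row["min_identity"] == pytest.approx(min(pid))
        assert row["max_identity"] == pytest.approx(max(pid))

    def test_singleton_undefined(self):
        ca = cluster_clades({"a": "ACGT" * 20})
        sim = within_clade_similarity(ca, {"a": "ACGT" * 20})
        assert np.isnan(sim.iloc[0]["min_identity"])


class TestCladeProfiles:
    def _assignment(self, mapping):
        from diazoquant.clades import CladeAssignment

        return CladeAssignment(0.95, mapping)

    def test_single_clade_fraction_one(self):
        counts = table({"a": [10, 20], "b": [5, 5]})
        prof = clade_profiles(counts, self._assignment({"a": "X", "b": "X"}))
        assert (prof.fractions["X"] == 1.0).all()

    def test_ninety_ten_split(self):
        counts = table({"a": [90], "b": [10]}, samples=["s0"])
        prof = clade_profiles(counts, self._assignment({"a": "X", "b": "Y"}))
        assert prof.fractions.loc["s0", "X"] == pytest.approx(0.9)
        assert prof.fractions.loc["s0", "Y"] == pytest.approx(0.1)

    def test_fractions_sum_to_one(self, rng):
        seqs, counts, truth = mutated_family(rng)
        ca = cluster_clades(seqs)
        prof = clade_profiles(counts, ca)
        assert np.allclose(prof.fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_marine1_aggregate(self):
        counts = table({"a": [80], "b": [12], "c": [8]}, samples=["s0"])
        prof = clade_profiles(
            counts, self._assignment({"a": "X", "b": "Y", "c": "Z"}), ["X", "Y"]
        )
        assert prof.marine1_fraction.loc["s0"] == pytest.approx(0.92)

    def test_zero_depth_sample_flagged(self):
        counts = table({"a": [10, 0], "b": [10, 0]})
        prof = clade_profiles(counts, self._assignment({"a": "X", "b": "Y"}))
        assert prof.empty_samples == ("s1",)
        assert prof.fractions.loc["s1"].isna().all()

    def test_unassigned_asv_rejected(self):
        counts = table({"a": [10], "b": [10]}, samples=["s0"])
        with pytest.raises(ValueError, match="without clade"):
            clade_profiles(counts, self._assignment({"a": "X"}))


class TestCodetection:
    def test_full_agreement(self):
        on = {"s1": True, "s2": True}
        grid, agreement = codetection_matrix(on, on, on)
        assert (agreement["disagree"] == 0).all()

    def test_fish_positive_sequencing_negative_is_discordant(self):
        grid, agreement = codetection_matrix(
            {"s1": False}, {"s1": False}, {"s1": True}
        )
        row = agreement[
            (agreement["method_a"] == "sequencing") & (agreement["method_b"] == "fish")
        ].iloc[0]
        assert row["disagree"] == 1

    def test_planted_discordance_count(self, rng):
        samples = [f"s{i}" for i in range(10)]
        seq = {s: True for s in samples}
        fish = dict(seq)
        for s in ("s2", "s5", "s7"):
            fish[s] = False
        grid, agreement = codetection_matrix(seq, seq, fish)
        row = agreement[
            (agreement["method_a"] == "sequencing") & (agreement["method_b"] == "fish")
        ].iloc[0]
        assert row["disagree"] == 3

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample sets"):
            codetection_matrix({"s1": True}, {"s2": True}, {"s1": True})
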