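"""Adapter trimming, read assignment, and per-position mutation profiling."""

import math
from collections import Counter

import numpy as np
import pytest

from trnamap import (
    ModificationSignature,
    PoolSpec,
    SimConfig,
    assign_reads,
    build_profile,
    call_modified_positions,
    profile_sample,
    simulate_sample,
    subtract_background,
    trim_adapter,
)
from trnamap.profiling import MutationProfile, summarize_references
from trnamap.simulate import DEFAULT_ADAPTER
from trnamap.trna import AnnotatedTRNA, rna_to_dna


class TestTrimAdapter:
    def test_internal_adapter_removed(self):
        read = "ACGT" + DEFAULT_ADAPTER + "GG"
        assert trim_adapter(read) == ("ACGT", True)

    def test_partial_terminal_adapter(self):
        read = "ACGTACGTAC" + DEFAULT_ADAPTER[:5]
        trimmed, found = trim_adapter(read, min_overlap=5)
        assert (trimmed, found) == ("ACGTACGTAC", True)

    def test_no_hit_flagged_unchanged(self):
        assert trim_adapter("ACGTACGTAC") == ("ACGTACGTAC", False)

    def test_agrees_with_brute_force_suffix_scan(self):
        """Oracle: test every suffix/prefix overlap explicitly."""
        adapter = "CTGTAGG"
        for core in ["AACCGGTT", "CTGT", ""]:
            for k in range(len(adapter) + 1):
                read = core + adapter[:k]
                # brute force: longest adapter prefix that terminates the read
                best = 0
                for j in range(1, len(adapter) + 1):
                    if j <= len(read) and read.endswith(adapter[:j]):
                        best = j
                expect_found = adapter in read or best >= 3
                trimmed, found = trim_adapter(read, adapter, min_overlap=3)
                assert found == expect_found
                if found and adapter not in read:
                    assert trimmed == read[: len(read) - best]

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT", adapter="")


class TestAssignReads:
    def test_exact_read_assigned_without_events(self, small_pool):
        read = rna_to_dna(small_pool[2].sequence)
        [a] = assign_reads([read], small_pool)
        assert a.reference_id == small_pool[2].id
        assert a.events == ()
        assert (a.start, a.end) == (0, len(read) - 1)

    def test_tie_between_references_unassigned(self):
        refs = [
            AnnotatedTRNA(id="r1", sequence="GGGGAAAACCCC", position_labels=tuple(map(str, range(12)))),
            AnnotatedTRNA(id="r2", sequence="GGGGAAAACCCG", position_labels=tuple(map(str, range(12)))),
        ]
        # read equidistant (1 mismatch each) from both references
        read = rna_to_dna("GGGGAAAACCCU")
        [a] = assign_reads([read], refs)
        assert not a.assigned

    def test_low_score_unassigned(self, small_pool):
        [a] = assign_reads(["T" * 40], small_pool, min_score_fraction=0.6)
        assert not a.assigned

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            assign_reads(["ACGT"], [])

    def test_mixture_recovered_exactly_from_error_free_reads(self, small_pool):
        pool = PoolSpec(members={t.id: w for t, w in zip(small_pool, [5, 3, 1, 1, 2, 4])})
        config = SimConfig(n_reads=1_000, error_rate=0.0, seed=31)
        reads, _ = simulate_sample(pool, [], small_pool, config, treated=False)
        trimmed = [trim_adapter(r.sequence)[0] for r in reads]
        assignments = assign_reads(trimmed, small_pool)
        got = Counter(a.reference_id for a in assignments)
        want = Counter(r.true_reference for r in reads)
        assert got == want

    def test_assigned_plus_unassigned_partition_reads(self, small_pool):
        config = SimConfig(n_reads=400, error_rate=0.05, seed=6)
        reads, _ = simulate_sample(
            PoolSpec.uniform([t.id for t in small_pool]), [], small_pool, config, treated=False
        )
        assignments = assign_reads([trim_adapter(r.sequence)[0] for r in reads], small_pool)
        n_assigned = sum(a.assigned for a in assignments)
        n_unassigned = sum(not a.assigned for a in assignments)
        assert n_assigned + n_unassigned == len(reads)

    def test_mismatch_event_reports_read_base(self, small_pool):
        t = small_pool[0]
        dna = list(rna_to_dna(t.sequence))
        dna[10] = "A" if dna[10] != "A" else "C"
        [a] = assign_reads(["".join(dna)], small_pool)
        assert a.reference_id == t.id
        assert (10, "mismatch", dna[10]) in a.events


class TestBuildProfile:
    def test_error_free_reads_give_zero_rates(self, small_pool):
        config = SimConfig(n_reads=2_000, error_rate=0.0, seed=12)
        reads, _ = simulate_sample(
            PoolSpec.uniform([small_pool[0].id]), [], small_pool[:1], config, treated=False
        )
        profiles, n_unassigned = profile_sample(reads, small_pool[:1], min_depth=1000)
        p = profiles[small_pool[0].id]
        assert n_unassigned == 0
        assert not p.missing.any()
        assert np.all(p.rate == 0)

    def test_depth_floor_flags_all_positions_missing(self, small_pool):
        config = SimConfig(n_reads=500, error_rate=0.0, seed=12)
        reads, _ = simulate_sample(
            PoolSpec.uniform([small_pool[0].id]), [], small_pool[:1], config, treated=False
        )
        profiles, _ = profile_sample(reads, small_pool[:1], min_depth=1000)
        p = profiles[small_pool[0].id]
        assert p.missing.all() and not p.analyzable
        assert not summarize_references(profiles)["analyzable"].iloc[0]

    def test_binomial_recovery_of_simulated_rate(self, small_pool):
        t = small_pool[4]
        rate, n = 0.3, 50_000
        sig = ModificationSignature(
            reference_id=t.id, position_label="22", misincorporation_rate=rate
        )
        config = SimConfig(n_reads=n, error_rate=0.0, seed=77)
        reads, _ = simulate_sample(PoolSpec.uniform([t.id]), [sig], [t], config, treated=True)
        profiles, _ = profile_sample(reads, [t], min_depth=1000)
        got = profiles[t.id].rate_at("22")
        assert abs(got - rate) < 3 * math.sqrt(rate * (1 - rate) / n)

    def test_deletion_counts_as_mutation(self, small_pool):
        t = small_pool[0]
        dna = rna_to_dna(t.sequence)
        # pick a position outside any homopolymer run so the deletion
        # placement in the optimal alignment is unambiguous
        idx = next(
            i for i in range(10, 40) if dna[i - 1] != dna[i] and dna[i + 1] != dna[i]
        )
        read = dna[:idx] + dna[idx + 1 :]
        assignments = assign_reads([read] * 5, [t])
        profiles = build_profile(assignments, [t], min_depth=1)
        p = profiles[t.id]
        assert p.mutation_count[idx] == 5
        assert p.rate[idx] == 1.0

    def test_insertions_excluded_from_rate_by_default(self, small_pool):
        t = small_pool[0]
        dna = rna_to_dna(t.sequence)
        read = dna[:30] + "A" + dna[30:]
        if read[30] == dna[30]:  # avoid an ambiguous homopolymer insertion
            read = dna[:30] + ("C" if dna[30] != "C" else "G") + dna[30:]
        assignments = assign_reads([read] * 3, [t])
        default = build_profile(assignments, [t], min_depth=1)[t.id]
        with_ins = build_profile(assignments, [t], min_depth=1, include_insertions=True)[t.id]
        assert default.mutation_count.sum() == 0
        assert with_ins.mutation_count.sum() == 3


class TestSubtraction:
    @staticmethod
    def profile(rates, missing=None, role="treated"):
        n = len(rates)
        return MutationProfile(
            reference_id="r",
            labels=tuple(str(i) for i in range(n)),
            depth=np.full(n, 5000),
            mutation_count=None,
            rate=np.asarray(rates, dtype=float),
            missing=np.asarray(missing if missing is not None else [False] * n),
            sample_role=role,
            min_depth=1000,
        )

    def test_subtraction_arithmetic_and_clamp(self):
        treated = self.profile([0.80, 0.00, 0.50])
        untreated = self.profile([0.01, 0.02, 0.50], role="untreated")
        sub = subtract_background(treated, untreated)
        assert sub.rate == pytest.approx([0.79, 0.0, 0.0])
        assert sub.sample_role == "subtracted"

    def test_missing_propagates(self):
        treated = self.profile([0.8, 0.8])
        untreated = self.profile([0.0, 0.0], missing=[False, True], role="untreated")
        sub = subtract_background(treated, untreated)
        assert list(sub.missing) == [False, True]

    def test_label_mismatch_rejected(self):
        a = self.profile([0.1])
        b = MutationProfile(
            reference_id="r",
            labels=("99",),
            depth=np.array([5000]),
            mutation_count=None,
            rate=np.array([0.0]),
            missing=np.array([False]),
        )
        with pytest.raises(ValueError, match="mismatch"):
            subtract_background(a, b)


class TestCallModifiedPositions:
    def test_strict_threshold_boundary(self):
        p = TestSubtraction.profile([0.011, 0.01, 0.0], role="subtracted")
        called = call_modified_positions({"r": p}, threshold=0.01)
        assert called == {("r", "0")}

    def test_all_zero_profile_empty(self):
        p = TestSubtraction.profile([0.0, 0.0], role="subtracted")
        assert call_modified_positions({"r": p}) == set()

    def test_missing_positions_never_called(self):
        p = TestSubtraction.profile([0.5, 0.5], missing=[True, False], role="subtracted")
        assert call_modified_positions({"r": p}) == {("r", "1")}

    def test_signature_positions_recovered_exactly_at_zero_error(self, small_pool):
        """At error 0, called positions equal the simulated signature positions."""
        refs = small_pool[:3]
        sigs = [
            ModificationSignature(reference_id=refs[0].id, position_label="22",
                                  misincorporation_rate=0.6),
            ModificationSignature(reference_id=refs[1].id, position_label="9",
                                  misincorporation_rate=0.3),
        ]
        pool = PoolSpec.uniform([t.id for t in refs])
        n = 12_000
        treated_reads, _ = simulate_sample(
            pool, sigs, refs, SimConfig(n_reads=n, error_rate=0.0, seed=51), treated=True
        )
        untreated_reads, _ = simulate_sample(
            pool, sigs, refs, SimConfig(n_reads=n, error_rate=0.0, seed=52), treated=False
        )
        pt, _ = profile_sample(treated_reads, refs, min_depth=1000, sample_role="treated")
        pu, _ = profile_sample(untreated_reads, refs, min_depth=1000, sample_role="untreated")
        sub = {rid: subtract_background(pt[rid], pu[rid]) for rid in pt}
        called = call_modified_positions(sub, threshold=0.01)
        assert called == {(refs[0].id, "22"), (refs[1].id, "9")}
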