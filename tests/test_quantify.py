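"""The EM engine and the four-step mass-preserving thresholding."""

import numpy as np
import pytest

from cedarquant.eqclass import ClassCollection, EquivalenceClass
from cedarquant.quantify import (
    AbundanceState,
    CedarModel,
    QuantOptions,
    critical_classes,
    em_iteration,
    greedy_set_cover,
    log_likelihood,
    mark_potentially_removable,
    quantify,
    remove_safe_pr,
    update_classes,
)

from conftest import make_refs, random_collection


def collection(class_specs, ref_ids, length=10000):
    classes = [
        EquivalenceClass(
            label=tuple(label),
            count=count,
            weights=np.asarray(weights, dtype=float),
            bin_signature=(0,) * len(label),
        )
        for label, count, weights in class_specs
    ]
    return ClassCollection(classes=classes, refs=make_refs(ref_ids, length))


def plain_em_oracle(class_specs, n_refs, iterations=1000):
    """Brute-force EM: uniform start, responsibility ∝ θ·w, θ ∝ est."""
    theta = np.full(n_refs, 1.0 / n_refs)
    for _ in range(iterations):
        est = np.zeros(n_refs)
        for label, count, weights in class_specs:
            vals = np.array([theta[i] * w for i, w in zip(label, weights)])
            est[list(label)] += count * vals / vals.sum()
        theta = est / est.sum()
    return est


class TestEmIteration:
    def test_symmetric_class_splits_evenly_and_is_fixed(self):
        col = collection([((0, 1), 10, (1.0, 1.0))], ["A", "B"])
        state = AbundanceState.uniform(col)
        for _ in range(5):
            state = em_iteration(state, col)
            np.testing.assert_allclose(state.est_reads, [5.0, 5.0])

    def test_unique_evidence_drains_the_shared_class(self):
        # classes {[A]:6, [A,B]:4}: fixed point a = 6 + 4a/(a+b) → (10, 0)
        specs = [((0,), 6, (1.0,)), ((0, 1), 4, (1.0, 1.0))]
        col = collection(specs, ["A", "B"])
        state = AbundanceState.uniform(col)
        for _ in range(1000):
            state = em_iteration(state, col)
        oracle = plain_em_oracle(specs, 2)
        np.testing.assert_allclose(state.est_reads, oracle, atol=1e-9)
        np.testing.assert_allclose(state.est_reads, [10.0, 0.0], atol=1e-3)

    def test_three_way_first_iteration_allocates_one_third(self):
        col = collection([((0, 1, 2), 1, (1.0, 1.0, 1.0))], ["A", "B", "C"])
        state = em_iteration(AbundanceState.uniform(col), col)
        assert [round(v, 2) for v in state.est_reads] == [0.33, 0.33, 0.33]

    def test_mass_preserved_each_iteration(self):
        rng = np.random.default_rng(5)
        col = random_collection(rng)
        total = col.total_fragments
        state = AbundanceState.uniform(col)
        for _ in range(20):
            state = em_iteration(state, col)
            assert state.est_reads.sum() == pytest.approx(total, abs=1e-6)

    def test_effective_length_shifts_nucleotide_allocation(self):
        # same read support, one reference twice as long: the longer one is
        # penalized as a prior from the second iteration on
        col = collection([((0, 1), 100, (1.0, 1.0))], ["short", "long"])
        col.refs.lengths = np.array([2000, 4000])
        state = AbundanceState.uniform(col)
        for _ in range(50):
            state = em_iteration(state, col)
        assert state.est_reads[0] > state.est_reads[1]
        assert state.est_reads.sum() == pytest.approx(100.0)


class TestThresholdingSteps:
    def test_mark_is_inclusive_at_the_cutoff(self):
        col = collection([((0, 1, 2), 1, (1.0, 1.0, 1.0))], ["A", "B", "C"])
        state = AbundanceState.uniform(col)
        state.est_reads = np.array([100.0, 2.0, 2.5])
        assert mark_potentially_removable(state, 2.0) == {1}

    def test_mark_cutoff_zero_marks_only_zero(self):
        col = collection([((0, 1), 1, (1.0, 1.0))], ["A", "B"])
        state = AbundanceState.uniform(col)
        state.est_reads = np.array([0.0, 0.4])
        assert mark_potentially_removable(state, 0.0) == {0}

    def test_safe_removal_requires_a_nonpr_guard_in_every_class(self):
        col = collection([((0, 1), 5, (1.0, 1.0))], ["X", "Y"])
        assert remove_safe_pr({0}, col) == {0}  # Y guards the class
        assert remove_safe_pr({0, 1}, col) == set()  # both PR: orphan risk

    def test_safe_removal_with_shared_guard(self):
        col = collection(
            [((0, 2), 3, (1.0, 1.0)), ((1, 2), 3, (1.0, 1.0))], ["X", "Y", "Z"]
        )
        assert remove_safe_pr({0, 1}, col) == {0, 1}  # Z guards both

    def test_update_classes_deletes_and_merges(self):
        col = collection(
            [((0, 1), 3, (1.0, 0.5)), ((0, 2), 2, (1.0, 0.5))], ["A", "B", "C"]
        )
        out = update_classes(col, {1, 2})
        assert len(out.classes) == 1
        assert out.classes[0].label == (0,)
        assert out.classes[0].count == 5
        assert out.total_fragments == col.total_fragments

    def test_update_classes_refuses_to_empty_a_class(self):
        col = collection([((0, 1), 3, (1.0, 1.0))], ["A", "B"])
        with pytest.raises(AssertionError):
            update_classes(col, {0, 1})


class TestGreedySetCover:
    def make_state(self, col, est):
        state = AbundanceState.uniform(col)
        state.est_reads = np.asarray(est, dtype=float)
        return state

    def test_island_hub_covers_everything(self):
        # worked example: G4 appears in every critical class of the island
        # {G4, G5, G6}; greedy keeps only G4 and removes G5 and G6
        col = collection(
            [
                ((0, 1), 1, (1.0, 1.0)),
                ((0, 2), 1, (1.0, 1.0)),
                ((0, 1, 2), 1, (1.0, 1.0, 1.0)),
            ],
            ["G4", "G5", "G6"],
        )
        state = self.make_state(col, [1.5, 0.8, 0.8])
        pr = {0, 1, 2}
        retained = greedy_set_cover(critical_classes(col, pr), pr, state, col.refs.ids)
        assert retained == {0}

    def test_single_critical_class_forces_its_member(self):
        col = collection([((0,), 1, (1.0,))], ["X"])
        state = self.make_state(col, [1.0])
        assert greedy_set_cover(critical_classes(col, {0}), {0}, state, col.refs.ids) == {0}

    def test_empty_critical_set_returns_empty(self):
        col = collection([((0,), 5, (1.0,))], ["X"])
        state = self.make_state(col, [5.0])
        assert greedy_set_cover([], {0}, state, col.refs.ids) == set()

    @staticmethod
    def greedy_oracle(critical_labels, candidates, est, ids):
        """Independently coded greedy trace with the same tie-break rule."""
        uncovered = list(range(len(critical_labels)))
        retained = []
        while uncovered:
            best = None
            for cand in candidates:
                if cand in retained:
                    continue
                gain = sum(1 for q in uncovered if cand in critical_labels[q])
                key = (-gain, -est[cand], ids[cand])
                if best is None or key < best[0]:
                    best = (key, cand)
            retained.append(best[1])
            uncovered = [q for q in uncovered if best[1] not in critical_labels[q]]
        return set(retained)

    def test_random_instances_match_greedy_trace_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_cand = int(rng.integers(2, 13))
            ids = [f"R{i:02d}" for i in range(n_cand)]
            n_classes = int(rng.integers(1, 21))
            specs = []
            seen = set()
            for _ in range(n_classes):
                size = int(rng.integers(1, min(4, n_cand) + 1))
                label = tuple(sorted(rng.choice(n_cand, size=size, replace=False).tolist()))
                if label in seen:
                    continue
                seen.add(label)
                specs.append((label, 1, tuple([1.0] * len(label))))
            col = collection(specs, ids)
            est = rng.uniform(0, 2, size=n_cand)
            state = self.make_state(col, est)
            candidates = set(range(n_cand))
            crit = critical_classes(col, candidates)
            got = greedy_set_cover(crit, candidates, state, ids)
            want = self.greedy_oracle([set(c.label) for c in crit], candidates, est, ids)
            assert got == want
            for c in crit:  # cover validity
                assert set(c.label) & got


class TestQuantify:
    def test_fig2_trace_reports_g2_g3_g4(self, fig2_collection):
        res = quantify(fig2_collection, QuantOptions(), trace=True)
        assert set(res.est_reads) == {"G2", "G3", "G4"}
        assert res.est_reads["G4"] == pytest.approx(3.0)
        reasons = {rid: reason for rid, reason, _ in res.removal_log}
        assert reasons == {"G5": "set-cover", "G6": "set-cover", "G1": "final-cutoff"}

    def test_unique_mappings_return_raw_counts(self):
        col = collection(
            [((0,), 40, (1.0,)), ((1,), 25, (1.0,)), ((2,), 7, (1.0,))],
            ["A", "B", "C"],
        )
        res = quantify(col)
        assert res.est_reads == {"A": 40.0, "B": 25.0, "C": 7.0}
        assert res.removal_log == []

    def test_low_abundance_identical_twins_resolve_to_one(self):
        # hand trace: est 2 each ≤ cutoff → both PR, the shared class is
        # critical, set-cover retains one twin; the survivor absorbs all 4
        # reads and passes the final cutoff
        col = collection([((0, 1), 4, (1.0, 1.0)), ((2,), 50, (1.0,))], ["twinA", "twinB", "C"])
        res = quantify(col, trace=True)
        twins = {k: v for k, v in res.est_reads.items() if k.startswith("twin")}
        assert len(twins) == 1
        assert list(twins.values())[0] == pytest.approx(4.0, rel=1e-6)
        assert ("twinB", "set-cover", 0) in res.removal_log or (
            "twinA",
            "set-cover",
            0,
        ) in res.removal_log

    def test_high_abundance_identical_twins_split_symmetrically(self):
        # identical references with abundant shared reads are above the PR
        # cutoff, so thresholding never fires and EM keeps the symmetric split
        col = collection([((0, 1), 1000, (1.0, 1.0))], ["twinA", "twinB"])
        res = quantify(col)
        assert res.est_reads == {"twinA": 500.0, "twinB": 500.0}

    def test_no_reported_reference_at_or_below_cutoff(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            col = random_collection(rng)
            res = quantify(col)
            assert all(v > 2.0 for v in res.est_reads.values())

    def test_mass_preserved_through_rounds_only_cutoff_discards(self):
        rng = np.random.default_rng(29)
        col = random_collection(rng)
        total = col.total_fragments
        res = quantify(col, trace=True)
        for m in res.trace.mass:
            assert m == pytest.approx(total, abs=1e-6)
        assert sum(res.est_reads.values()) + res.discarded_mass == pytest.approx(total, abs=1e-6)

    def test_loglik_nondecreasing_within_stretches(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            col = random_collection(rng)
            res = quantify(col, trace=True)
            ll, st = res.trace.loglik, res.trace.stretch
            for i in range(1, len(ll)):
                if st[i] == st[i - 1]:
                    assert ll[i] >= ll[i - 1] - 1e-8

    def test_rounds_bounded_by_reference_count(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            col = random_collection(rng)
            res = quantify(col, trace=True)
            assert res.trace.n_rounds <= len(col.refs)

    def test_empty_collection_rejected(self):
        refs = make_refs(["A"])
        with pytest.raises(ValueError):
            CedarModel(ClassCollection(classes=[], refs=refs))

    def test_results_surface(self, fig2_collection):
        res = CedarModel(fig2_collection).fit(trace=True)
        df = res.frame()
        assert list(df.columns) == [
            "reference_id", "taxid", "length", "effective_length",
            "estimated_reads", "read_fraction", "nucleotide_fraction",
        ]
        assert df.read_fraction.sum() <= 1.0 + 1e-9
        assert df.nucleotide_fraction.sum() == pytest.approx(1.0)
        text = res.summary()
        assert "total mapped fragments" in text and "G4" in text

    def test_class_order_invariance(self):
        rng = np.random.default_rng(41)
        col = random_collection(rng)
        res1 = quantify(col)
        shuffled = ClassCollection(
            classes=[col.classes[i] for i in rng.permutation(len(col.classes))],
            refs=col.refs,
        )
        res2 = quantify(shuffled)
        assert set(res1.est_reads) == set(res2.est_reads)
        for k in res1.est_reads:
            assert res1.est_reads[k] == pytest.approx(res2.est_reads[k], abs=1e-6)
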