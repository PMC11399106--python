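"""Mutual-information conflict detection against brute-force oracles."""

import math

import numpy as np
import pytest

from rnaswitch.conflict import (
    assemble_stems,
    collect_base_pairs,
    find_conflicting_pairs,
    mi_table,
    mutual_information,
    predict_switch,
    select_conflicting_base_pairs,
    stems_conflict,
)
from rnaswitch.core import (
    ContractViolation,
    FoldEnsemble,
    RnaSequence,
    SecondaryStructure,
    Stem,
)
from rnaswitch.fixtures import recovers_designed


def oracle_mi(p, q) -> float:
    """Independent plug-in MI from explicit joint counts (bits)."""
    n = len(p)
    joint = {}
    for a, b in zip(p, q):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    pm = {v: sum(c for (a, _), c in joint.items() if a == v) / n for v in (0, 1)}
    qm = {v: sum(c for (_, b), c in joint.items() if b == v) / n for v in (0, 1)}
    total = 0.0
    for (a, b), c in joint.items():
        pj = c / n
        total += pj * math.log2(pj / (pm[a] * qm[b]))
    return total


class TestMutualInformation:
    def test_identical_balanced_vectors_give_one_bit(self):
        v = np.array([1, 1, 0, 0])
        assert mutual_information(v, v) == pytest.approx(1.0)

    def test_independent_vectors_give_zero(self):
        assert mutual_information(
            np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])
        ) == pytest.approx(0.0)

    def test_known_value(self):
        got = mutual_information(np.array([1, 1, 1, 0]), np.array([1, 1, 0, 0]))
        assert got == pytest.approx(0.311278, abs=1e-5)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 40)
            p = rng.integers(0, 2, size=n)
            q = rng.integers(0, 2, size=n)
            assert mutual_information(p, q) == pytest.approx(
                oracle_mi(p, q), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractViolation):
            mutual_information(np.array([1, 0]), np.array([1, 0, 1]))

    def test_table_matches_pairwise_calls_and_k_conservation(self):
        rng = np.random.default_rng(3)
        presences = []

        class BP:
            def __init__(self, pair, vec):
                self.pair, self.presence = pair, vec

        for k in range(12):
            presences.append(BP((k, k + 10), rng.integers(0, 2, 50).astype(np.uint8)))
        table = mi_table(presences)
        for a in range(12):
            for b in range(12):
                expected = (
                    0.0
                    if a == b
                    else mutual_information(
                        presences[a].presence, presences[b].presence
                    )
                )
                assert table.mi[a, b] == pytest.approx(expected, abs=1e-12)
        # sum of K = twice the upper-triangle MI mass
        upper = sum(
            table.mi[a, b] for a in range(12) for b in range(a + 1, 12)
        )
        assert table.k_sums.sum() == pytest.approx(2 * upper, abs=1e-9)


class TestCollectBasePairs:
    def _ensemble(self, seq, structures):
        return FoldEnsemble(sequence=seq, structures=structures)

    def test_frequency_filter(self):
        seq = RnaSequence("x", "GGGAAACCC")
        always = SecondaryStructure.from_pairs([(0, 8)])
        sometimes = SecondaryStructure.from_pairs([(0, 8), (1, 7)])
        ens = self._ensemble(seq, [always] * 5 + [sometimes] * 5)
        got = collect_base_pairs(ens, 0.05, 0.95)
        assert [bp.pair for bp in got] == [(1, 7)]
        assert got[0].frequency == pytest.approx(0.5)

    def test_matches_brute_force_occurrence_scan(self, backend):
        seq = RnaSequence("x", "GCAUGGCAUGCCAUG")
        structures = backend.sample(seq, 200, seed=5)
        ens = self._ensemble(seq, structures)
        got = {bp.pair: bp.frequency for bp in collect_base_pairs(ens, 0.05, 0.95)}
        # oracle: count every pair by scanning every structure
        counts = {}
        for s in structures:
            for pr in s.pairs:
                counts[pr] = counts.get(pr, 0) + 1
        expected = {
            pr: c / 200 for pr, c in counts.items() if 0.05 <= c / 200 <= 0.95
        }
        assert got == pytest.approx(expected)

    def test_bad_bounds_rejected(self, bistable_ensemble):
        with pytest.raises(ContractViolation):
            collect_base_pairs(bistable_ensemble, 0.9, 0.1)


class TestThresholdAndStems:
    def test_u_threshold_example(self):
        class T:
            pairs = [(0, 9), (1, 8), (2, 7)]
            k_sums = np.array([2.0, 1.0, 0.3])

        assert select_conflicting_base_pairs(T, 0.5) == [0, 1]

    def test_single_pair_always_retained(self):
        class T:
            pairs = [(0, 9)]
            k_sums = np.array([0.7])

        assert select_conflicting_base_pairs(T, 0.5) == [0]

    def test_threshold_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(500):
            m = rng.integers(1, 20)
            k = rng.random(m)

            class T:
                pairs = [(a, a + 10) for a in range(m)]
                k_sums = k

            u = float(rng.uniform(0.1, 1.0))
            got = select_conflicting_base_pairs(T, u)
            expected = [a for a in range(m) if k[a] >= u * k.max()]
            assert got == expected

    def test_stem_assembly_merges_adjacent_pairs(self):
        pairs = [(2, 20), (3, 19), (4, 18), (5, 17)]
        stems = assemble_stems(pairs, min_len=3)
        assert [s.intervals for s in stems] == [((2, 5), (17, 20))]
        assert stems[0].length == 4

    def test_stem_length_filter_is_strict(self):
        pairs = [(2, 20), (3, 19), (4, 18)]
        assert assemble_stems(pairs, min_len=3) == []

    def test_stem_assembly_matches_brute_force_runs(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            pairs = set()
            for _ in range(rng.integers(1, 25)):
                i = int(rng.integers(0, 20))
                j = int(rng.integers(i + 5, 60))
                pairs.add((i, j))
            got = {s.intervals for s in assemble_stems(sorted(pairs), min_len=0)}
            # oracle: group pairs by diagonal (i + j), find consecutive runs
            bydiag = {}
            for i, j in pairs:
                bydiag.setdefault(i + j, []).append((i, j))
            expected = set()
            for diag, ps in bydiag.items():
                ps.sort()
                run = [ps[0]]
                for pr in ps[1:]:
                    if pr[0] == run[-1][0] + 1:
                        run.append(pr)
                    else:
                        expected.add(
                            ((run[0][0], run[-1][0]), (run[-1][1], run[0][1]))
                        )
                        run = [pr]
                expected.add(((run[0][0], run[-1][0]), (run[-1][1], run[0][1])))
            assert got == expected


class TestConflictingPairs:
    def test_overlap_example_conflicting(self):
        s1 = Stem(((2, 5), (17, 20)))
        s2 = Stem(((2, 5), (30, 33)))
        assert stems_conflict(s1, s2) == 4  # > 3: conflicting

    def test_overlap_of_three_is_not_conflicting(self):
        s1 = Stem(((2, 5), (17, 20)))
        s2 = Stem(((3, 6), (30, 33)))
        k = {p: 1.0 for p in s1.pairs + s2.pairs}
        assert find_conflicting_pairs([s1, s2], k, overlap_threshold=3) == []

    def test_matches_brute_force_on_random_stems(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            stems = []
            for _ in range(10):
                u = int(rng.integers(0, 30))
                ln = int(rng.integers(1, 6))
                x = int(rng.integers(u + ln + 3, u + ln + 40))
                stems.append(Stem(((u, u + ln - 1), (x, x + ln - 1))))
            k = {}
            for s in stems:
                for p in s.pairs:
                    k.setdefault(p, float(rng.random()))
            got = find_conflicting_pairs(stems, k, overlap_threshold=3)
            # oracle: all-pairs strict-overlap check + sort
            def overlap(a, b):
                return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)

            expected = []
            for a in range(len(stems)):
                for b in range(a + 1, len(stems)):
                    s1, s2 = stems[a], stems[b]
                    if s1.intervals > s2.intervals:
                        s1, s2 = s2, s1
                    ov = max(
                        overlap(i1, i2)
                        for i1 in s1.intervals
                        for i2 in s2.intervals
                    )
                    if ov > 3:
                        ks = [k[p] for p in s1.pairs + s2.pairs]
                        expected.append((s1, s2, float(np.mean(ks))))
            expected.sort(
                key=lambda t: (
                    -t[2],
                    t[0].intervals[0][0],
                    t[0].intervals[1][0],
                    t[1].intervals[0][0],
                )
            )
            assert [
                (c.stem1.intervals, c.stem2.intervals, pytest.approx(c.score))
                for c in got
            ] == [(s1.intervals, s2.intervals, sc) for s1, s2, sc in expected]


class TestPredictSwitch:
    def test_unpairable_sequence_yields_no_switch(self, config):
        assert predict_switch(RnaSequence("a", "AAAA"), config=config) is None

    def test_recovers_designed_bistable_pair(
        self, bistable, bistable_prediction
    ):
        assert recovers_designed(bistable_prediction, bistable)
        # both recovered stems overlap in the shared central box
        assert bistable_prediction.overlap_len > 3

    def test_reported_stems_are_mutually_exclusive(self, bistable_prediction):
        pos1 = bistable_prediction.stem1.positions()
        pos2 = bistable_prediction.stem2.positions()
        assert pos1 & pos2  # stems share arm positions, so cannot co-occur

    def test_deterministic_given_seed(self, bistable, config, backend):
        a = predict_switch(bistable.sequence, config=config, backend=backend, seed=3)
        b = predict_switch(bistable.sequence, config=config, backend=backend, seed=3)
        assert a.as_dict() == b.as_dict()

    def test_invariant_to_structure_order(self, bistable, bistable_ensemble, config):
        from rnaswitch.core import FoldEnsemble

        rev = FoldEnsemble(
            sequence=bistable_ensemble.sequence,
            structures=list(reversed(bistable_ensemble.structures)),
        )
        a = predict_switch(bistable.sequence, config=config, ensemble=bistable_ensemble)
        b = predict_switch(bistable.sequence, config=config, ensemble=rev)
        assert a.as_dict() == b.as_dict()
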