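"""Sort-seq screen scoring: normalization, chi-squared, switch scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rnaswitch.core import ContractViolation
from rnaswitch.fixtures import simulate_screen_counts
from rnaswitch.screen import (
    N_BINS,
    ScreenCounts,
    call_significant_switches,
    functional_effect_test,
    mutagenesis_score,
    normalize_median_of_ratios,
)


def counts_from_matrix(matrix: dict) -> ScreenCounts:
    """matrix: variant -> {(bin, rep): count}"""
    rows = []
    for variant, cells in matrix.items():
        for (b, rep), c in cells.items():
            rows.append(
                {"variant": variant, "bin": b, "replicate": rep, "count": c}
            )
    return ScreenCounts(table=pd.DataFrame(rows))


def oracle_median_of_ratios(arr):
    """Independent implementation of the DESeq recipe."""
    keep = (arr > 0).all(axis=1)
    logs = np.log(arr[keep])
    ref = np.exp(logs.mean(axis=1))
    return np.median(arr[keep] / ref[:, None], axis=0)


class TestNormalization:
    def test_identical_samples_have_unit_factors(self):
        sc = counts_from_matrix(
            {
                "v1": {(1, 1): 10, (1, 2): 10},
                "v2": {(1, 1): 30, (1, 2): 30},
            }
        )
        nc = normalize_median_of_ratios(sc)
        assert np.allclose(nc.size_factors.values, [1.0, 1.0])

    def test_hand_computed_two_sample_case(self):
        sc = counts_from_matrix(
            {
                "a": {(1, 1): 10, (1, 2): 20},
                "b": {(1, 1): 20, (1, 2): 40},
                "c": {(1, 1): 30, (1, 2): 60},
            }
        )
        nc = normalize_median_of_ratios(sc)
        assert np.allclose(nc.size_factors.values, [0.70710678, 1.41421356])
        # normalized counts equal across the two samples
        assert np.allclose(
            nc.normalized[(1, 1)].values, nc.normalized[(1, 2)].values
        )

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            nv, ns = int(rng.integers(3, 12)), int(rng.integers(2, 6))
            arr = rng.integers(0, 50, size=(nv, ns)).astype(float)
            if not (arr > 0).all(axis=1).any():
                arr[0] = rng.integers(1, 50, ns)
            matrix = {
                f"v{i}": {(1 + s % N_BINS, 1 + s // N_BINS): arr[i, s]
                          for s in range(ns)}
                for i in range(nv)
            }
            sc = counts_from_matrix(matrix)
            nc = normalize_median_of_ratios(sc)
            m = sc.matrix().to_numpy(dtype=float)
            assert np.allclose(
                nc.size_factors.values, oracle_median_of_ratios(m), atol=1e-12
            )

    def test_depth_invariance_of_bin_distributions(self):
        counts, _ = simulate_screen_counts(n_variants=10, seed=1)
        nc1 = normalize_median_of_ratios(counts)
        scaled = counts.table.copy()
        mask = (scaled["bin"] == 3) & (scaled["replicate"] == 1)
        scaled.loc[mask, "count"] *= 5  # sequencing depth jump in one sample
        nc2 = normalize_median_of_ratios(ScreenCounts(table=scaled))
        v = counts.table["variant"].iloc[0]
        assert np.allclose(
            nc1.bin_distribution(v, 1), nc2.bin_distribution(v, 1), atol=1e-9
        )

    def test_all_zero_variant_set_is_unnormalizable(self):
        sc = counts_from_matrix(
            {"a": {(1, 1): 0, (1, 2): 5}, "b": {(1, 1): 3, (1, 2): 0}}
        )
        with pytest.raises(ContractViolation, match="un-normalizable"):
            normalize_median_of_ratios(sc)

    def test_ninth_bin_rejected(self):
        with pytest.raises(ContractViolation, match="bin labels"):
            counts_from_matrix({"a": {(9, 1): 5}})


class TestFunctionalEffect:
    def _nc(self, bins, reps=1):
        # three constant reference variants pin every size factor at 1,
        # so the tested variant's normalized counts equal its raw counts
        matrix = {"v": {}, "r1": {}, "r2": {}, "r3": {}}
        for rep in range(1, reps + 1):
            for b in range(1, N_BINS + 1):
                matrix["v"][(b, rep)] = bins[b - 1]
                for r in ("r1", "r2", "r3"):
                    matrix[r][(b, rep)] = 10
        return normalize_median_of_ratios(counts_from_matrix(matrix))

    def test_uniform_distribution_gives_zero_statistic(self):
        nc = self._nc([10] * 8)
        chi2, p, _ = functional_effect_test(nc, "v")
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fully_concentrated_distribution(self):
        nc = self._nc([80, 0, 0, 0, 0, 0, 0, 0])
        chi2, p, direction = functional_effect_test(nc, "v")
        assert chi2 == pytest.approx(560.0)
        assert direction == -1  # mass at the low-expression end

    def test_matches_textbook_chisquare(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            bins = rng.integers(0, 40, N_BINS)
            if bins.sum() == 0:
                continue
            nc = self._nc(list(bins))
            chi2, p, _ = functional_effect_test(nc, "v")
            e = bins.sum() / N_BINS
            expected = float(((bins - e) ** 2 / e).sum())
            assert chi2 == pytest.approx(expected, abs=1e-9)
            assert p == pytest.approx(stats.chi2.sf(expected, df=7), abs=1e-12)

    def test_null_type_one_error_calibration(self):
        """Uniform multinomial draws reject at ~alpha."""
        rng = np.random.default_rng(3)
        n_sims, alpha = 2000, 0.05
        rejections = 0
        draws = rng.multinomial(400, [1 / N_BINS] * N_BINS, size=n_sims)
        for row in draws:
            chi2, p = stats.chisquare(row)
            rejections += p < alpha
        assert 0.03 < rejections / n_sims < 0.07


class TestMutagenesisScore:
    def _quartet_nc(self, profiles):
        # constant reference variants pin size factors at 1 so raw
        # profiles survive normalization unchanged
        matrix = {r: {} for r in ("r1", "r2", "r3", "r4", "r5")}
        for cls, prof in profiles.items():
            matrix[cls] = {}
        for rep in (1, 2):
            for b in range(1, N_BINS + 1):
                for cls, prof in profiles.items():
                    matrix[cls][(b, rep)] = prof[b - 1]
                for r in ("r1", "r2", "r3", "r4", "r5"):
                    matrix[r][(b, rep)] = 10
        return normalize_median_of_ratios(counts_from_matrix(matrix))

    def test_extremal_concordant_quartet_scores_two(self):
        # linear ramps: corr(A,B) = corr(C,D) = 1, corr(A,C) = corr(A,D) = -1
        low = [80, 70, 60, 50, 40, 30, 20, 10]
        high = list(reversed(low))
        nc = self._quartet_nc({"A": low, "B": low, "C": high, "D": high})
        vs = mutagenesis_score(nc, "A", "B", "C", "D")
        assert vs.correlations[0] == pytest.approx(1.0)
        assert vs.correlations[1] == pytest.approx(1.0)
        assert vs.correlations[2] == pytest.approx(-1.0)
        assert vs.correlations[3] == pytest.approx(-1.0)
        assert vs.score == pytest.approx(2.0)

    def test_identical_variants_score_zero(self):
        prof = [5, 10, 20, 30, 20, 10, 5, 2]
        nc = self._quartet_nc({c: prof for c in "ABCD"})
        vs = mutagenesis_score(nc, "A", "B", "C", "D")
        assert all(c == pytest.approx(1.0) for c in vs.correlations)
        assert vs.score == pytest.approx(0.0)

    def test_constant_vector_yields_undefined_marker(self):
        prof = [7] * 8
        other = [5, 10, 20, 30, 20, 10, 5, 2]
        nc = self._quartet_nc({"A": prof, "B": other, "C": other, "D": other})
        vs = mutagenesis_score(nc, "A", "B", "C", "D")
        assert vs.correlations[0] is None
        assert np.isnan(vs.score)

    def test_null_quartets_center_on_zero(self):
        rng = np.random.default_rng(4)
        scores = []
        prof = np.array([2, 6, 14, 22, 22, 14, 6, 2], dtype=float)
        prof /= prof.sum()
        for _ in range(400):
            draws = {c: rng.multinomial(2000, prof, size=2) for c in "ABCD"}
            matrix = {}
            for c in "ABCD":
                matrix[c] = {}
                for rep in (1, 2):
                    for b in range(1, N_BINS + 1):
                        matrix[c][(b, rep)] = draws[c][rep - 1][b - 1]
            nc = normalize_median_of_ratios(counts_from_matrix(matrix))
            scores.append(mutagenesis_score(nc, "A", "B", "C", "D").score)
        assert abs(float(np.mean(scores))) < 0.05


class TestSignificanceCall:
    def test_hand_computed_threshold(self):
        scores = [1.0, 0.0, 0.0, 0.0, 0.0]
        flags = call_significant_switches(scores)
        # mean 0.2, sd ~0.447 -> threshold ~0.647: only the first flagged
        assert flags == [True, False, False, False, False]

    def test_equal_scores_flag_nothing(self):
        assert call_significant_switches([0.3] * 6) == [False] * 6

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        scores = list(rng.normal(0, 1, 30))
        flags = call_significant_switches(scores)
        perm = rng.permutation(30)
        flags_perm = call_significant_switches([scores[i] for i in perm])
        assert [flags[i] for i in perm] == flags_perm

    def test_nan_scores_excluded_and_never_flagged(self):
        flags = call_significant_switches([float("nan"), 2.0, 0.0, 0.0])
        assert flags[0] is False and flags[1] is True

    def test_too_few_finite_scores_rejected(self):
        with pytest.raises(ContractViolation):
            call_significant_switches([1.0, float("nan")])


class TestRecoveryOnSimulatedScreen:
    def test_true_switches_recovered_with_few_false_flags(self):
        counts, truth = simulate_screen_counts(
            n_variants=200, effect_size=1.0, depth=5000, seed=7
        )
        nc = normalize_median_of_ratios(counts)
        scores = []
        for cand in sorted(truth):
            scores.append(
                mutagenesis_score(
                    nc, *(f"{cand}_{c}" for c in "ABCD"), variant=cand
                )
            )
        flags = call_significant_switches(scores)
        tp = sum(1 for s, f in zip(scores, flags) if f and truth[s.variant])
        fp = sum(1 for s, f in zip(scores, flags) if f and not truth[s.variant])
        n_true = sum(truth.values())
        assert tp / n_true >= 0.9
        assert fp / (len(scores) - n_true) <= 0.1
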