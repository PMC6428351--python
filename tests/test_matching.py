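from __future__ import annotations

import numpy as np
import pytest

from oracles import kld_direct
from phosmod.matching import (
    MatchParams,
    PWM,
    _batch_kld,
    _shuffled_batch,
    default_flank_positions,
    kld,
    match_kinases,
    pwm_from_intensities,
    pwm_from_windows,
    shuffle_pwm,
)


def column_pwm(*probs, positions=None):
    """Single- or multi-column PWM with given leading probabilities; the
    remainder of each 20-row column is zero."""
    cols = []
    for p in probs:
        col = np.zeros(20)
        col[: len(p)] = p
        cols.append(col)
    positions = positions or tuple(range(1, len(cols) + 1))
    return PWM(tuple(positions), np.column_stack(cols))


def random_pwm(rng, n_positions=12, positions=None):
    mat = rng.dirichlet(np.ones(20), size=n_positions).T
    mat /= mat.sum(axis=0)
    return PWM(positions or default_flank_positions(n_positions + 1), mat)


class TestPwmFromIntensities:
    def test_direct_normalization(self):
        mat = np.zeros((20, 1))
        mat[:3, 0] = [2.0, 1.0, 1.0]
        pwm = pwm_from_intensities(mat, [1], pseudocount=0.0)
        np.testing.assert_allclose(pwm.matrix[:3, 0], [0.5, 0.25, 0.25])

    def test_all_zero_column_with_pseudocount(self):
        pwm = pwm_from_intensities(np.zeros((20, 1)), [1], pseudocount=0.01)
        np.testing.assert_allclose(pwm.matrix[:, 0], 0.05)

    def test_pseudocount_arithmetic(self):
        mat = np.zeros((20, 1))
        mat[:3, 0] = [2.0, 1.0, 1.0]
        pwm = pwm_from_intensities(mat, [1], pseudocount=0.01)
        total = 4.0 + 20 * 0.01
        np.testing.assert_allclose(
            pwm.matrix[:4, 0],
            [2.01 / total, 1.01 / total, 1.01 / total, 0.01 / total],
        )

    def test_all_zero_column_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_intensities(np.zeros((20, 1)), [1], pseudocount=0.0)

    def test_negative_intensity_rejected(self):
        mat = np.zeros((20, 1))
        mat[0, 0] = -1
        with pytest.raises(ValueError):
            pwm_from_intensities(mat, [1])


class TestPwmFromWindows:
    def _windows(self):
        # position -3 (index 3): 8x R, 2x K; everything else A
        base = "AAA{0}AASAAAAAA"
        return [base.format("R")] * 8 + [base.format("K")] * 2

    def test_counts_without_pseudocount(self):
        pwm = pwm_from_windows(self._windows(), pseudocount=0.0)
        j = pwm.positions.index(-3)
        from phosmod.io import AA_INDEX

        assert pwm.matrix[AA_INDEX["R"], j] == pytest.approx(0.8)
        assert pwm.matrix[AA_INDEX["K"], j] == pytest.approx(0.2)

    def test_counts_with_pseudocount(self):
        pwm = pwm_from_windows(self._windows(), pseudocount=0.5)
        from phosmod.io import AA_INDEX

        j = pwm.positions.index(-3)
        col = pwm.matrix[:, j]
        assert col[AA_INDEX["R"]] == pytest.approx(8.5 / 20)
        assert col[AA_INDEX["K"]] == pytest.approx(2.5 / 20)
        assert col.sum() == pytest.approx(1.0)

    def test_single_window_point_mass(self):
        pwm = pwm_from_windows(["AAARAASAAAAAA"], pseudocount=0.0)
        assert set(np.unique(pwm.matrix)) == {0.0, 1.0}

    def test_pads_excluded_from_counts(self):
        pwm = pwm_from_windows(["---RAASAAAAAA", "AAARAASAAAAAA"], pseudocount=0.0)
        from phosmod.io import AA_INDEX

        j = pwm.positions.index(-6)
        assert pwm.matrix[AA_INDEX["A"], j] == pytest.approx(1.0)  # 1 of 1 non-pad

    def test_all_pad_position_rejected(self):
        with pytest.raises(ValueError, match="-6"):
            pwm_from_windows(["---RAASAAAAAA"], pseudocount=0.0)


class TestKld:
    def test_identical_is_zero(self, rng):
        p = random_pwm(rng)
        assert kld(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_symbol_column(self):
        p = column_pwm([0.5, 0.5])
        q = column_pwm([0.25, 0.75])
        assert kld(p, q) == pytest.approx(0.2075187496, abs=1e-9)

    def test_asymmetric_case(self):
        p = column_pwm([0.75, 0.25])
        q = column_pwm([0.25, 0.75])
        assert kld(p, q) == pytest.approx(0.7924812504, abs=1e-9)

    def test_agrees_with_direct_formula(self, rng):
        p, q = random_pwm(rng), random_pwm(rng)
        expected = kld_direct(p.matrix.T.tolist(), q.matrix.T.tolist())
        assert kld(p, q) == pytest.approx(expected, abs=1e-10)

    def test_restricted_to_common_positions(self, rng):
        p = random_pwm(rng, 12)  # positions -6..6 \ {0}
        spot_positions = tuple(x for x in range(-5, 5) if x != 0)  # -5..+4 \ {0}
        q = random_pwm(rng, 9, positions=spot_positions)
        expected = sum(
            kld(
                PWM((pos,), p.matrix[:, [p.positions.index(pos)]]),
                PWM((pos,), q.matrix[:, [q.positions.index(pos)]]),
            )
            for pos in q.positions
        )
        assert kld(p, q) == pytest.approx(expected, abs=1e-9)

    def test_no_common_positions_rejected(self):
        with pytest.raises(ValueError):
            kld(column_pwm([1.0], positions=(1,)), column_pwm([1.0], positions=(2,)))

    def test_zero_in_q_where_p_positive_rejected(self):
        with pytest.raises(ValueError):
            kld(column_pwm([0.5, 0.5]), column_pwm([1.0, 0.0]))


class TestShufflePwm:
    def test_column_multisets_preserved(self, rng):
        pwm = random_pwm(rng)
        shuffled = shuffle_pwm(pwm, rng)
        ours = np.sort(shuffled.matrix, axis=0)
        theirs = np.sort(pwm.matrix, axis=0)
        # columns may have moved: compare as multisets of sorted columns
        assert sorted(map(tuple, ours.T)) == sorted(map(tuple, theirs.T))
        np.testing.assert_allclose(shuffled.matrix.sum(axis=0), 1.0)
        assert shuffled.positions == pwm.positions

    def test_seeded_reproducibility(self, rng):
        pwm = random_pwm(rng)
        a = shuffle_pwm(pwm, np.random.default_rng(7))
        b = shuffle_pwm(pwm, np.random.default_rng(7))
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_batch_matches_single_shuffle_invariants(self, rng):
        pwm = random_pwm(rng)
        batch = _shuffled_batch(pwm.matrix, 50, rng)
        assert batch.shape == (50, 20, 12)
        for mat in batch[:5]:
            assert sorted(map(tuple, np.sort(mat, axis=0).T)) == sorted(
                map(tuple, np.sort(pwm.matrix, axis=0).T)
            )
        np.testing.assert_allclose(batch.sum(axis=1), 1.0)

    def test_batch_kld_equals_scalar_kld(self, rng):
        p = random_pwm(rng)
        qs = [random_pwm(rng) for _ in range(5)]
        batch = np.stack([q.matrix for q in qs])
        np.testing.assert_allclose(
            _batch_kld(p.matrix, batch), [kld(p, q) for q in qs], atol=1e-10
        )


class TestMatchKinases:
    def _library(self, rng, n=4):
        return {f"K{i}": random_pwm(rng) for i in range(n)}

    def test_exact_match_has_fdr_zero(self, rng):
        lib = self._library(rng)
        module_pwm = lib["K0"]
        results = match_kinases(
            {"m1": module_pwm}, lib, {"m1": ["K0"]},
            MatchParams(n_shuffles=50, rng_seed=0),
        )
        assert len(results) == 1
        assert results[0].kld == pytest.approx(0.0, abs=1e-12)
        assert results[0].fdr == 0.0

    def test_null_size_bookkeeping(self, rng):
        lib = self._library(rng, n=4)
        results = match_kinases(
            {"m1": random_pwm(rng)}, lib, {"m1": ["K1"]},
            MatchParams(n_shuffles=25, rng_seed=0),
        )
        assert results[0].null_size == 25 * 4

    def test_per_kinase_null(self, rng):
        lib = self._library(rng, n=4)
        results = match_kinases(
            {"m1": random_pwm(rng)}, lib, {"m1": ["K1"]},
            MatchParams(n_shuffles=25, rng_seed=0, null="per-kinase"),
        )
        assert results[0].null_size == 25

    def test_fdr_counting_rule(self):
        from phosmod.matching import MatchResult

        r = MatchResult("K", "m", kld=1.0, null_size=1000, n_null_smaller=50)
        assert r.fdr == 0.05

    def test_candidate_absent_from_library_skipped(self, rng):
        lib = self._library(rng)
        results = match_kinases(
            {"m1": random_pwm(rng)}, lib, {"m1": ["K0", "K999"]},
            MatchParams(n_shuffles=10, rng_seed=0),
        )
        assert [r.kinase for r in results] == ["K0"]

    def test_seeded_determinism(self, rng):
        lib = self._library(rng)
        module_pwms = {"m1": random_pwm(rng), "m2": random_pwm(rng)}
        cands = {"m1": ["K0", "K2"], "m2": ["K1"]}
        params = MatchParams(n_shuffles=30, rng_seed=9)
        a = match_kinases(module_pwms, lib, cands, params)
        b = match_kinases(module_pwms, lib, cands, params)
        assert a == b

    def test_params_validation(self):
        with pytest.raises(ValueError):
            MatchParams(n_shuffles=0)
        with pytest.raises(ValueError):
            MatchParams(null="bogus")
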