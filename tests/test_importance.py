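"""Sensitivity coefficients, deleterious-mutation fractions, and rank logic."""

import numpy as np
import pytest

from causaldrift.model import PARAM_NAMES, PhenotypeRecord
from causaldrift.importance import (
    fdel_vs_S_correlation,
    fraction_deleterious,
    grid_fraction_deleterious,
    mutation_effect_distribution,
    rank_by_magnitude,
    rank_distribution,
    rank_fdel,
    robustness_profile,
    sensitivity,
    sensitivity_profile,
)


class PowerLawStub:
    """U proportional to a product of powers of the rate constants, so the
    exact sensitivity S of parameter j to a relative change d is
    ((1+d)**a_j - 1)/d."""

    def __init__(self, exponents):
        self.exponents = np.asarray(exponents, dtype=float)

    def evaluate(self, rates):
        U = 800.0 * np.prod(np.asarray(rates) ** self.exponents)
        return PhenotypeRecord(U, "normal" if U > 691.26 else
                               ("diseased" if U < 502.86 else "intermediate"),
                               10.0, True)


class TestSensitivity:
    def test_zero_when_uptake_unchanged(self):
        stub = PowerLawStub(np.zeros(15))
        assert sensitivity(stub, np.ones(15), 3) == 0.0

    def test_matches_analytic_power_law(self):
        exps = np.zeros(15)
        exps[2], exps[7] = 0.5, -1.2
        stub = PowerLawStub(exps)
        base = np.ones(15)
        for j, a in [(2, 0.5), (7, -1.2), (11, 0.0)]:
            expected = (1.1 ** a - 1.0) / 0.1
            assert sensitivity(stub, base, j) == pytest.approx(expected, rel=1e-9)

    def test_agrees_with_central_difference_oracle(self, circuit, viable_sets):
        mat, records = viable_sets
        compared = 0
        for rates, rec in zip(mat[:5], records[:5]):
            for j in (0, 6, 14):
                S_fwd = sensitivity(circuit, rates, j, U_base=rec.U)
                # independent central-difference estimate at small delta
                hi, lo = rates.copy(), rates.copy()
                hi[j] *= 1.001
                lo[j] *= 0.999
                U_hi, U_lo = circuit.evaluate(hi).U, circuit.evaluate(lo).U
                S_ctr = ((U_hi - U_lo) / rec.U) / 0.002
                if abs(S_ctr) < 1e-4:   # below the forward-difference noise floor
                    continue
                assert abs(S_fwd) == pytest.approx(abs(S_ctr), rel=1.0)
                assert np.sign(S_fwd) == np.sign(S_ctr)
                compared += 1
        assert compared >= 5


class TestRanking:
    def test_rank_is_permutation_and_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        vals = 10.0 ** rng.uniform(-10, 0, 15)
        ranks = rank_by_magnitude(vals)
        assert sorted(ranks) == list(range(1, 16))
        order = np.argsort(-vals, kind="stable")
        for pos, j in enumerate(order):
            assert ranks[j] == pos + 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.random(15)
        assert np.array_equal(rank_by_magnitude(vals),
                              rank_by_magnitude(vals * 17.3))

    def test_tie_break_deterministic(self):
        vals = np.array([1.0, 2.0] + [0.5] * 13)
        r1, r2 = rank_by_magnitude(vals), rank_by_magnitude(vals)
        assert np.array_equal(r1, r2)
        assert r1[1] == 1 and r1[0] == 2
        # canonical order among tied values
        assert list(r1[2:]) == list(range(3, 16))

    def test_profile_ranks(self, circuit, viable_sets):
        mat, _ = viable_sets
        prof = sensitivity_profile(circuit, mat[0])
        assert [r.parameter for r in prof] == list(PARAM_NAMES)
        assert sorted(r.rank for r in prof) == list(range(1, 16))
        abs_S = np.array([r.abs_S for r in prof])
        assert np.array_equal([r.rank for r in prof], rank_by_magnitude(abs_S))

    def test_fdel_zero_ties_share_lowest_rank(self):
        f = np.array([0.4, 0.0, 0.1] + [0.0] * 12)
        ranks = rank_fdel(f)
        assert ranks[0] == 1 and ranks[2] == 2
        assert all(ranks[j] == 15 for j in range(15) if f[j] == 0)


class TestFractionDeleterious:
    def test_count_identity_and_range(self, circuit, viable_sets):
        mat, _ = viable_sets
        rng = np.random.default_rng(2)
        rec = fraction_deleterious(circuit, mat[0], 6, rng, n_mutations=25)
        assert 0.0 <= rec.f_del <= 1.0
        assert rec.f_del * rec.n_mutations == pytest.approx(
            round(rec.f_del * rec.n_mutations))

    def test_estimator_unbiased_on_known_measure(self):
        # parameter 0 deleterious iff log10 p0 < -1: measure q = 1/3
        class StepStub:
            def evaluate(self, rates):
                bad = np.log10(rates[0]) < -1.0
                return PhenotypeRecord(100.0 if bad else 1000.0,
                                       "diseased" if bad else "normal", 10.0, True)

        rng = np.random.default_rng(3)
        fs = [fraction_deleterious(StepStub(), np.ones(15), 0, rng,
                                   n_mutations=60).f_del for _ in range(30)]
        se = np.sqrt((1 / 3) * (2 / 3) / (60 * 30))
        assert np.mean(fs) == pytest.approx(1 / 3, abs=4 * se)

    def test_grid_oracle_agreement(self, circuit, viable_sets):
        mat, _ = viable_sets
        rng = np.random.default_rng(4)
        for j in (5, 11):
            mc = fraction_deleterious(circuit, mat[1], j, rng, n_mutations=60)
            grid = grid_fraction_deleterious(circuit, mat[1], j, n_grid=100)
            se = np.sqrt(max(grid * (1 - grid), 1 / 60) / 60)
            assert mc.f_del == pytest.approx(grid, abs=3 * se)


class TestMutationEffects:
    def test_majority_of_mutations_are_modest_on_circuit(self, circuit,
                                                         viable_sets):
        mat, _ = viable_sets
        rng = np.random.default_rng(9)
        vals = mutation_effect_distribution(circuit, mat, rng)
        assert np.all(vals >= 0)
        # most single-parameter randomizations change uptake by less than
        # the wild-type uptake itself (log10 |dU/U| <= 0)
        assert np.mean(vals <= 1.0) > 0.5

    def test_nonnegative_and_identity_control(self):
        exps = np.full(15, 0.2)
        stub = PowerLawStub(exps)
        rng = np.random.default_rng(5)
        vals = mutation_effect_distribution(stub, np.ones((50, 15)), rng)
        assert len(vals) == 50 and np.all(vals >= 0)
        # re-assigning the identical value leaves U exactly unchanged
        base = np.ones(15)
        U_wt = stub.evaluate(base).U
        assert abs(stub.evaluate(base.copy()).U - U_wt) == 0.0


class TestAggregation:
    def test_rank_histogram_recount_oracle(self):
        rng = np.random.default_rng(6)
        ranks = np.array([rng.permutation(15) + 1 for _ in range(40)])
        hist, ranges = rank_distribution(ranks)
        assert (hist.sum(axis=1) == 40).all()
        # brute-force recount of one histogram
        j = 4
        for r in range(1, 16):
            assert hist.iloc[j, r - 1] == int((ranks[:, j] == r).sum())
        assert (ranges["min_rank"] >= 1).all() and (ranges["max_rank"] <= 15).all()

    def test_fdel_s_correlation_signs(self):
        n = 120
        rng = np.random.default_rng(7)
        s = rng.random((n, 15))
        mono = fdel_vs_S_correlation(s, s + 1.0)
        anti = fdel_vs_S_correlation(s, -s)
        assert np.allclose(mono["R"], 1.0)
        assert np.allclose(anti["R"], -1.0)

    def test_constant_column_missing(self):
        n = 120
        rng = np.random.default_rng(8)
        s = rng.random((n, 15))
        f = s.copy()
        f[:, 3] = 0.0
        out = fdel_vs_S_correlation(f, s)
        assert np.isnan(out.loc[PARAM_NAMES[3], "R"])
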