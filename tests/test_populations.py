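"""Random-walk control populations, single-mutation cases, and the
regression importance machinery."""

import numpy as np
import pytest
from scipy import stats

from causaldrift.populations import (
    PopulationPair,
    Individual,
    _glm_importance,
    _variance_decomposition_xy,
    build_pair,
    derive_cases,
    linear_importance,
    log10_wald_p,
    logistic_importance,
    random_walk_population,
    variance_decomposition,
)


@pytest.fixture(scope="module")
def small_pair(stub_circuit):
    rng = np.random.default_rng(10)
    founder = 10.0 ** np.full(15, 1.5)  # well inside the stub's normal region
    return build_pair(stub_circuit, founder, rng, n_walks=10, walk_length=10)


class TestRandomWalk:
    def test_contracts(self, stub_circuit):
        rng = np.random.default_rng(0)
        founder = 10.0 ** np.full(15, 1.5)
        controls = random_walk_population(stub_circuit, founder, rng,
                                          n_walks=5, walk_length=10)
        assert len(controls) == 50
        assert all(c.phenotype_class == "normal" for c in controls)
        assert all(c.binary_code == 1 for c in controls)

    def test_walk_distance_from_founder(self, stub_circuit):
        rng = np.random.default_rng(1)
        founder = 10.0 ** np.full(15, 1.5)
        controls = random_walk_population(stub_circuit, founder, rng,
                                          n_walks=1, walk_length=10)
        n_diff_prev = np.inf
        for k, c in enumerate(controls, start=1):
            n_diff = int(np.sum(c.rates != founder))
            assert n_diff <= k
            if k == 1:
                assert n_diff == 1
        # parent links chain back to the founder
        assert controls[0].parent_id == -1
        for prev, cur in zip(controls, controls[1:]):
            assert cur.parent_id == prev.individual_id
            assert int(np.sum(cur.rates != prev.rates)) == 1

    def test_retry_budget(self, stub_circuit):
        founder = 10.0 ** np.full(15, 1.5)

        class NeverNormal:
            phenotype_cfg = stub_circuit.phenotype_cfg

            def evaluate(self, rates):
                from causaldrift.model import PhenotypeRecord
                return PhenotypeRecord(100.0, "diseased", 10.0, True)

        with pytest.raises(RuntimeError):
            random_walk_population(NeverNormal(), founder,
                                   np.random.default_rng(0), n_walks=1,
                                   walk_length=1, retry_budget=20)


class TestDeriveCases:
    def test_contracts(self, stub_circuit, small_pair):
        controls = {c.individual_id: c for c in small_pair.controls}
        assert len(small_pair.cases) == len(small_pair.controls)
        for case in small_pair.cases:
            assert case.phenotype_class == "diseased"
            assert case.binary_code == 0
            assert case.U < stub_circuit.phenotype_cfg.U_minus
            parent = controls[case.parent_id]
            assert int(np.sum(case.rates != parent.rates)) == 1

    def test_empty_controls_rejected(self, stub_circuit):
        with pytest.raises(ValueError):
            derive_cases(stub_circuit, [], np.random.default_rng(0), 10)


class TestLogisticImportance:
    def test_generative_recovery(self):
        """Coefficient signs and significance ordering recovered from data
        generated by a known sparse logistic model."""
        rng = np.random.default_rng(3)
        n = 2000
        X = rng.normal(size=(n, 15))
        beta_true = np.zeros(15)
        beta_true[1], beta_true[8] = 2.0, -1.5
        p = 1.0 / (1.0 + np.exp(-(X @ beta_true)))
        y = (rng.random(n) < p).astype(float)
        results = _glm_importance(X, y, logistic=True)
        by_name = {r.parameter: r for r in results}
        names = [r.parameter for r in results]
        assert np.sign(by_name[names[1]].beta) == 1
        assert np.sign(by_name[names[8]].beta) == -1
        true_p = [results[1].log10_p, results[8].log10_p]
        null_p = [results[j].log10_p for j in range(15) if j not in (1, 8)]
        assert max(true_p) < min(null_p)
        assert results[1].significant and results[8].significant

    def test_permutation_null_significance_rate(self):
        rng = np.random.default_rng(4)
        n = 400
        X = rng.normal(size=(n, 15))
        hits = total = 0
        for _ in range(30):
            y = rng.permutation(np.repeat([0.0, 1.0], n // 2))
            for r in _glm_importance(X, y, logistic=True):
                hits += r.significant
                total += 1
        frac = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert frac == pytest.approx(0.05, abs=4 * se + 0.01)

    def test_ranks_are_permutation(self, small_pair):
        results = logistic_importance(small_pair)
        assert sorted(r.rank for r in results) == list(range(1, 16))

    def test_zero_variance_predictor_missing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 15))
        X[:, 7] = 1.23
        y = (rng.random(300) < 0.5).astype(float)
        results = _glm_importance(X, y, logistic=True)
        assert np.isnan(results[7].beta) and results[7].flagged

    def test_separation_flagged_not_crashed(self):
        # y determined exactly by the sign of one predictor: perfect separation
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 15))
        y = (X[:, 0] > 0).astype(float)
        results = _glm_importance(X, y, logistic=True)
        assert all(r.flagged for r in results)
        # the separating predictor still carries an extreme p-value bound
        assert results[0].log10_p < -10


class TestExtremePValues:
    def test_log_tail_against_asymptotic_oracle(self):
        # Mills-ratio asymptotic series for the normal tail, valid at large z
        for z in (10.0, 20.0, 30.0):
            phi = np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
            tail = phi / z * (1 - 1 / z**2 + 3 / z**4 - 15 / z**6)
            expected = np.log10(2 * tail)
            assert log10_wald_p(z) == pytest.approx(expected, rel=1e-6)

    def test_no_underflow_far_out(self):
        lp = log10_wald_p(np.array([100.0, 700.0]))
        assert np.all(np.isfinite(lp))
        assert lp[1] < -100000 / 2.303  # far beyond float underflow of p


class TestLinearImportance:
    def test_exact_linear_response(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(500, 15))
        beta = rng.normal(size=15)
        y = 3.0 + X @ beta
        results = _glm_importance(X, y, logistic=False)
        assert all(r.significant for r in results)
        for j, r in enumerate(results):
            assert r.beta == pytest.approx(beta[j], abs=1e-8)

    def test_matches_normal_equations_oracle(self, small_pair):
        X, _, U = small_pair.design()
        results = linear_importance(small_pair)
        Xd = np.column_stack([np.ones(len(X)), X])
        beta_oracle = np.linalg.solve(Xd.T @ Xd, Xd.T @ U)
        for j, r in enumerate(results):
            assert r.beta == pytest.approx(beta_oracle[j + 1], rel=1e-8, abs=1e-10)


class TestVarianceDecomposition:
    def test_purely_additive_response(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 15))
        y = X @ rng.normal(size=15) + 0.1 * rng.normal(size=400)
        vd = _variance_decomposition_xy(X, y)
        assert 0.0 <= vd.R2_additive <= vd.R2_with_pairwise <= 1.0
        assert vd.delta_R2 < 0.02

    def test_single_product_response(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(400, 15))
        y = X[:, 2] * X[:, 9] + 0.05 * rng.normal(size=400)
        vd = _variance_decomposition_xy(X, y)
        assert vd.delta_R2 > 0.5

    def test_on_population_pair(self, small_pair):
        vd = variance_decomposition(small_pair)
        assert 0.0 <= vd.R2_additive <= vd.R2_with_pairwise <= 1.0
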