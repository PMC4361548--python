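import numpy as np
import pytest

from causaldrift import InsulinCircuit, PhenotypeConfig
from causaldrift.model import PhenotypeRecord
from causaldrift.sampling import SamplingConfig, sample_viable


class StubCircuit:
    """Analytic phenotype map with the same interface as InsulinCircuit.

    U is a logistic ramp in a weighted sum of the log10 rate constants, so
    classification logic, walks, case derivation and selection can be tested
    without ODE integrations.  Genotypes with large positive scores are
    normal, large negative scores diseased.
    """

    def __init__(self, weights=None, U_max=2400.0):
        self.phenotype_cfg = PhenotypeConfig()
        if weights is None:
            # concentrated weights so that a single full-range mutation of a
            # leading parameter can flip the class (as in the real circuit)
            weights = np.zeros(15)
            weights[:5] = [0.45, 0.25, 0.15, 0.10, 0.05]
        self.weights = np.asarray(weights)
        self.U_max = U_max
        self.n_integrations = 0

    def uptake_of(self, rates):
        score = self.weights @ np.log10(np.asarray(rates, dtype=float))
        return self.U_max / (1.0 + np.exp(-3.0 * score))

    def evaluate(self, rates):
        self.n_integrations += 1
        U = self.uptake_of(rates)
        cfg = self.phenotype_cfg
        if U < cfg.U_minus:
            cls = "diseased"
        elif U > cfg.U_plus:
            cls = "normal"
        else:
            cls = "intermediate"
        return PhenotypeRecord(U, cls, t_max=10.0, regulation_ok=True)


@pytest.fixture(scope="session")
def circuit():
    return InsulinCircuit()


@pytest.fixture(scope="session")
def stub_circuit():
    return StubCircuit()


@pytest.fixture(scope="session")
def viable_sets(circuit):
    """A small cached collection of normal-class genotypes."""
    mat, records, _ = sample_viable(
        circuit, 20, SamplingConfig(n_samples=1, seed=2024))
    return mat, records
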