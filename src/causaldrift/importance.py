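"""Per-background importance of the 15 rate constants.

Two complementary measures, both evaluated on a fixed genetic background
(one viable genotype):

* the sensitivity coefficient S = (dU/U)/(dp/p), estimated by a one-sided
  +10% perturbation of the focal rate constant, and
* f_del, the fraction of full-range log-uniform randomizations of the focal
  constant that push the uptake below the disease threshold.

Ranks run from 1 (largest |S|, or largest f_del) to 15.  For f_del, every
parameter tied at f_del = 0 gets the lowest possible rank of 15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._kernel import N_PARAM
from .model import PARAM_NAMES

__all__ = [
    "SensitivityRecord",
    "RobustnessRecord",
    "sensitivity",
    "sensitivity_profile",
    "rank_by_magnitude",
    "fraction_deleterious",
    "robustness_profile",
    "rank_fdel",
    "mutation_effect_distribution",
    "rank_distribution",
    "fdel_vs_S_correlation",
    "importance_study",
]

ABS_S_FLOOR = 1e-300  # floor for log displays of |S| = 0


@dataclass(frozen=True)
class SensitivityRecord:
    set_id: int
    parameter: str
    S: float
    abs_S: float
    rank: int


@dataclass(frozen=True)
class RobustnessRecord:
    set_id: int
    parameter: str
    f_del: float
    n_mutations: int
    rank: int


def sensitivity(circuit, rates, index: int, delta: float = 0.1,
                U_base: float | None = None) -> float:
    """Signed sensitivity coefficient of parameter ``index`` at ``rates``.

    Returns NaN (logged on the record level) if either integration fails.
    """
    rates = np.asarray(rates, dtype=float)
    if U_base is None:
        base = circuit.evaluate(rates)
        if base.failed or base.U <= 0:
            return np.nan
        U_base = base.U
    perturbed = rates.copy()
    perturbed[index] *= 1.0 + delta
    rec = circuit.evaluate(perturbed)
    if rec.failed:
        return np.nan
    return ((rec.U - U_base) / U_base) / delta


def rank_by_magnitude(abs_values: np.ndarray) -> np.ndarray:
    """Rank 1 = largest magnitude; ties broken by canonical parameter order."""
    order = np.lexsort((np.arange(len(abs_values)), -np.asarray(abs_values)))
    ranks = np.empty(len(abs_values), dtype=int)
    ranks[order] = np.arange(1, len(abs_values) + 1)
    return ranks


def sensitivity_profile(circuit, rates, set_id: int = 0,
                        delta: float = 0.1) -> list[SensitivityRecord]:
    """S for all 15 parameters on one base genotype, with |S| ranks."""
    rates = np.asarray(rates, dtype=float)
    base = circuit.evaluate(rates)
    if base.failed or base.U <= 0:
        raise ValueError("base genotype must integrate successfully with U > 0")
    S = np.array([sensitivity(circuit, rates, j, delta, U_base=base.U)
                  for j in range(N_PARAM)])
    ranks = rank_by_magnitude(np.abs(np.nan_to_num(S, nan=0.0)))
    return [SensitivityRecord(set_id, PARAM_NAMES[j], float(S[j]),
                              float(abs(S[j])), int(ranks[j]))
            for j in range(N_PARAM)]


def fraction_deleterious(circuit, rates, index: int, rng: np.random.Generator,
                         n_mutations: int = 100, set_id: int = 0,
                         log10_lower: float = -3.0,
                         log10_upper: float = 3.0) -> RobustnessRecord:
    """Fraction of random full-range redraws of one parameter that yield a
    diseased uptake (U < U_minus).  Failed integrations are excluded from
    the denominator."""
    rates = np.asarray(rates, dtype=float)
    n_del = 0
    n_eval = 0
    for _ in range(n_mutations):
        mutant = rates.copy()
        mutant[index] = 10.0 ** rng.uniform(log10_lower, log10_upper)
        rec = circuit.evaluate(mutant)
        if rec.failed:
            continue
        n_eval += 1
        if rec.is_diseased:
            n_del += 1
    f_del = n_del / n_eval if n_eval else np.nan
    return RobustnessRecord(set_id, PARAM_NAMES[index], float(f_del), n_eval, rank=0)


def rank_fdel(f_del: np.ndarray) -> np.ndarray:
    """Ranks for f_del: 1 = largest; all parameters with f_del = 0 share the
    lowest possible rank of 15."""
    ranks = rank_by_magnitude(f_del)
    ranks[np.asarray(f_del) == 0] = N_PARAM
    return ranks


def robustness_profile(circuit, rates, rng: np.random.Generator,
                       n_mutations: int = 100, set_id: int = 0) -> list[RobustnessRecord]:
    """f_del for all 15 parameters on one base genotype, with ranks."""
    recs = [fraction_deleterious(circuit, rates, j, rng, n_mutations, set_id)
            for j in range(N_PARAM)]
    ranks = rank_fdel(np.array([r.f_del for r in recs]))
    return [RobustnessRecord(r.set_id, r.parameter, r.f_del, r.n_mutations,
                             int(k)) for r, k in zip(recs, ranks)]


def grid_fraction_deleterious(circuit, rates, index: int, n_grid: int = 100,
                              log10_lower: float = -3.0,
                              log10_upper: float = 3.0) -> float:
    """Deterministic oracle for f_del: equally spaced log10 grid scan."""
    rates = np.asarray(rates, dtype=float)
    n_del = 0
    n_eval = 0
    for x in np.linspace(log10_lower, log10_upper, n_grid):
        mutant = rates.copy()
        mutant[index] = 10.0 ** x
        rec = circuit.evaluate(mutant)
        if rec.failed:
            continue
        n_eval += 1
        n_del += rec.is_diseased
    return n_del / n_eval if n_eval else np.nan


def mutation_effect_distribution(circuit, viable_params: np.ndarray,
                                 rng: np.random.Generator,
                                 log10_lower: float = -3.0,
                                 log10_upper: float = 3.0) -> np.ndarray:
    """|dU/U_wt| when one random parameter of each base genotype is
    randomized once over the full sampling range."""
    viable_params = np.asarray(viable_params, dtype=float)
    if viable_params.shape[0] < 1:
        raise ValueError("need at least one base genotype")
    out = []
    for base in viable_params:
        U_wt = circuit.evaluate(base).U
        mutant = base.copy()
        j = rng.integers(N_PARAM)
        mutant[j] = 10.0 ** rng.uniform(log10_lower, log10_upper)
        rec = circuit.evaluate(mutant)
        if rec.failed or not np.isfinite(U_wt):
            continue
        out.append(abs((rec.U - U_wt) / U_wt))
    return np.asarray(out)


def rank_distribution(ranks: np.ndarray):
    """Per-parameter histogram of ranks 1..15 across sets, plus the attained
    (min, max) rank.  ``ranks`` is (n_sets, 15)."""
    import pandas as pd

    ranks = np.asarray(ranks, dtype=int)
    counts = np.zeros((N_PARAM, N_PARAM), dtype=int)  # [param, rank-1]
    for j in range(N_PARAM):
        for r in range(1, N_PARAM + 1):
            counts[j, r - 1] = int(np.sum(ranks[:, j] == r))
    hist = pd.DataFrame(counts, index=list(PARAM_NAMES),
                        columns=[f"rank_{r}" for r in range(1, N_PARAM + 1)])
    ranges = pd.DataFrame({
        "min_rank": ranks.min(axis=0), "max_rank": ranks.max(axis=0),
    }, index=list(PARAM_NAMES))
    return hist, ranges


def fdel_vs_S_correlation(f_del: np.ndarray, abs_S: np.ndarray):
    """Per-parameter Spearman correlation of f_del with |S| across sets.

    Both arrays are (n_sets, 15).  Constant columns give NaN.
    """
    import pandas as pd

    rows = []
    for j, name in enumerate(PARAM_NAMES):
        x, y = f_del[:, j], abs_S[:, j]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rows.append({"parameter": name, "R": np.nan, "p": np.nan})
            continue
        res = stats.spearmanr(x[ok], y[ok])
        rows.append({"parameter": name, "R": float(res.statistic),
                     "p": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("parameter")


def importance_study(circuit, viable_params: np.ndarray,
                     rng: np.random.Generator, n_mutations: int = 100,
                     with_fdel: bool = True):
    """Sensitivity (and optionally robustness) profiles for a collection of
    viable genotypes; returns a tidy DataFrame, one row per (set, parameter)."""
    import pandas as pd

    rows = []
    for i, base in enumerate(np.asarray(viable_params, dtype=float)):
        sens = sensitivity_profile(circuit, base, set_id=i)
        if with_fdel:
            rob = robustness_profile(circuit, base, rng, n_mutations, set_id=i)
        for j in range(N_PARAM):
            row = {"set_id": i, "parameter": PARAM_NAMES[j],
                   "S": sens[j].S, "abs_S": sens[j].abs_S,
                   "rank_S": sens[j].rank}
            if with_fdel:
                row.update(f_del=rob[j].f_del, n_mut=rob[j].n_mutations,
                           rank_fdel=rob[j].rank)
            rows.append(row)
    return pd.DataFrame(rows)
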