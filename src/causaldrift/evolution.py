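"""Mutation-selection simulation under stabilizing selection for normal
glucose uptake, with per-generation sensitivity tracking.

Each generation, every individual in a population of N genotypes has one
uniformly chosen rate constant re-randomized (log-uniform over the full
sampling range); the next generation is then filled by sampling mutated
individuals with replacement, admitting only those with a normal phenotype.
The sensitivity coefficient S of all 15 parameters is evaluated each
generation at a representative genotype — by default the individual at a
fixed population index ("tracked"), or optionally the component-wise
geometric mean of the population (the arithmetic mean in log10 space).
The tracked individual turns over every generation with the population and
so decorrelates at the population's own rate; the mean genotype averages
over the whole population and decorrelates roughly twofold slower.

Causal-drift statistics come from the autocorrelation of log10|S| per
parameter and its decay time: the smallest lag tau >= 2 at which rho(tau)
first drops below half of rho(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernel import N_PARAM
from .importance import ABS_S_FLOOR, rank_by_magnitude, sensitivity_profile
from .model import PARAM_NAMES

__all__ = [
    "EvolutionConfig",
    "EvolutionTrace",
    "evolve",
    "autocorrelation",
    "autocorrelation_curve",
    "decay_time",
    "evolution_summary",
]


@dataclass(frozen=True)
class EvolutionConfig:
    N: int = 100                     # population size
    generations: int = 500
    seed: int = 0
    representative: str = "tracked"  # "tracked" individual | "mean" genotype
    tracked_index: int = 0
    log10_lower: float = -3.0
    log10_upper: float = 3.0
    max_lag: int = 50

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("population size must be >= 2")
        if self.generations < 2:
            raise ValueError("need at least 2 generations")
        if self.representative not in ("mean", "tracked"):
            raise ValueError("representative must be 'mean' or 'tracked'")


@dataclass
class EvolutionTrace:
    S: np.ndarray                     # (generations, 15), signed
    ranks: np.ndarray                 # (generations, 15), 1 = largest |S|
    n_viable_mutants: np.ndarray      # per generation
    fallback_generations: list = field(default_factory=list)
    config: EvolutionConfig | None = None

    @property
    def abs_S(self) -> np.ndarray:
        return np.abs(self.S)

    @property
    def log_abs_S(self) -> np.ndarray:
        return np.log10(np.maximum(self.abs_S, ABS_S_FLOOR))


def evolve(circuit, founder, cfg: EvolutionConfig) -> EvolutionTrace:
    """Run the mutation-selection cycle and record per-generation S.

    If a generation produces no viable mutant at all, selection falls back
    to the pre-mutation population for that generation (recorded in
    ``fallback_generations``).
    """
    founder = np.asarray(founder, dtype=float)
    if not circuit.evaluate(founder).is_normal:
        raise ValueError("founder must have a normal phenotype")
    rng = np.random.default_rng(cfg.seed)
    pop = np.tile(founder, (cfg.N, 1))

    S = np.empty((cfg.generations, N_PARAM))
    ranks = np.empty((cfg.generations, N_PARAM), dtype=int)
    n_viable = np.empty(cfg.generations, dtype=int)
    fallbacks = []

    for gen in range(cfg.generations):
        # mutation: exactly one randomized parameter per individual
        mutated = pop.copy()
        idx = rng.integers(N_PARAM, size=cfg.N)
        mutated[np.arange(cfg.N), idx] = 10.0 ** rng.uniform(
            cfg.log10_lower, cfg.log10_upper, cfg.N)

        viable = np.array([circuit.evaluate(m).is_normal for m in mutated])
        n_viable[gen] = viable.sum()
        if n_viable[gen] == 0:
            fallbacks.append(gen)
        else:
            # sampling with replacement, admitting only normal phenotypes,
            # is uniform over the viable mutants
            chosen = rng.choice(np.flatnonzero(viable), size=cfg.N, replace=True)
            pop = mutated[chosen]

        rep = _representative(pop, cfg)
        profile = sensitivity_profile(circuit, rep)
        S[gen] = [r.S for r in profile]
        ranks[gen] = rank_by_magnitude(np.abs(np.nan_to_num(S[gen], nan=0.0)))

    return EvolutionTrace(S, ranks, n_viable, fallbacks, cfg)


def _representative(pop: np.ndarray, cfg: EvolutionConfig) -> np.ndarray:
    if cfg.representative == "tracked":
        return pop[cfg.tracked_index]
    return 10.0 ** np.mean(np.log10(pop), axis=0)


def autocorrelation(series: np.ndarray, tau: int) -> float:
    """Lag-``tau`` sample autocorrelation: lagged sample covariance over
    the overall sample variance (mean-subtracted)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if not 0 <= tau < n:
        raise ValueError("need series length > tau >= 0")
    m = x.mean()
    var = np.sum((x - m) ** 2)
    if var == 0:
        return np.nan
    if tau == 0:
        return 1.0
    cov = np.sum((x[tau:] - m) * (x[:-tau] - m))
    return float(cov / var)


def autocorrelation_curve(series: np.ndarray, max_lag: int = 50) -> np.ndarray:
    max_lag = min(max_lag, len(series) - 1)
    return np.array([autocorrelation(series, t) for t in range(max_lag + 1)])


def decay_time(rho: np.ndarray):
    """Smallest lag tau >= 2 with rho(tau) < rho(1)/2.

    Returns ``(tau_half, censored)``; if the curve never crosses within the
    computed lags the value is censored at the last lag.
    """
    rho = np.asarray(rho, dtype=float)
    if len(rho) < 3:
        raise ValueError("need rho defined at least for lags 0..2")
    half = rho[1] / 2.0
    for tau in range(2, len(rho)):
        if rho[tau] < half:
            return tau, False
    return len(rho) - 1, True


def evolution_summary(trace: EvolutionTrace):
    """Per-parameter decay time of the log10|S| autocorrelation.

    Censored decay times are excluded from the mean and flagged.
    """
    import pandas as pd

    max_lag = trace.config.max_lag if trace.config else 50
    rows = []
    curves = {}
    for j, name in enumerate(PARAM_NAMES):
        rho = autocorrelation_curve(trace.log_abs_S[:, j], max_lag)
        curves[name] = rho
        tau, censored = decay_time(rho)
        rows.append({"parameter": name, "tau_half": tau, "censored": censored,
                     "rho1": rho[1]})
    df = pd.DataFrame(rows).set_index("parameter")
    valid = df.loc[~df["censored"], "tau_half"]
    stats = {
        "mean_tau_half": float(valid.mean()) if len(valid) else np.nan,
        "min_tau_half": int(df["tau_half"].min()),
        "max_tau_half": int(df["tau_half"].max()),
        "n_censored": int(df["censored"].sum()),
    }
    return df, curves, stats
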