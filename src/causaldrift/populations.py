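"""Case-control 'populations' of related genotypes and regression-based
importance.

Controls are built by a viability-constrained random walk: starting from a
normal-class founder, one randomly chosen rate constant is re-randomized
(log-uniform over the full range) and the move is retried until the result
is again normal-class; each walk records 10 successively more distant
members, and 100 restarted walks give 1000 related controls.  Cases are
derived by mutating a single randomly chosen parameter of a random control
until the uptake falls below the disease threshold.

Importance of a parameter in a population pair is the Wald p-value of its
coefficient in a joint multiple logistic (binary phenotype) or linear
(continuous uptake) regression on the log10 rate constants.  p-values are
computed in log space, so values down to ~1e-300 are resolved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._kernel import N_PARAM
from .model import PARAM_NAMES

__all__ = [
    "Individual",
    "PopulationPair",
    "RegressionResult",
    "VarianceDecomposition",
    "random_walk_population",
    "derive_cases",
    "build_pair",
    "logistic_importance",
    "linear_importance",
    "variance_decomposition",
    "pair_study",
    "log10_wald_p",
]

_LN10 = np.log(10.0)


@dataclass
class Individual:
    individual_id: int
    parent_id: int | None
    role: str                  # "control" | "case"
    rates: np.ndarray
    U: float
    phenotype_class: str

    @property
    def binary_code(self) -> int:
        return 1 if self.role == "control" else 0


@dataclass
class PopulationPair:
    pair_id: int
    founder: np.ndarray
    controls: list[Individual] = field(default_factory=list)
    cases: list[Individual] = field(default_factory=list)

    def design(self):
        """(X, y, U): log10 genotypes, binary code, uptake for all members."""
        members = self.controls + self.cases
        X = np.log10(np.array([m.rates for m in members]))
        y = np.array([m.binary_code for m in members], dtype=float)
        U = np.array([m.U for m in members])
        return X, y, U


@dataclass(frozen=True)
class RegressionResult:
    parameter: str
    beta: float
    log10_p: float             # log10 of the two-sided Wald p-value
    rank: int                  # 1 = most significant
    significant: bool          # p <= 0.05
    flagged: bool = False      # separation / zero variance / fit failure


@dataclass(frozen=True)
class VarianceDecomposition:
    R2_additive: float
    R2_with_pairwise: float
    flagged: bool = False

    @property
    def delta_R2(self) -> float:
        return self.R2_with_pairwise - self.R2_additive


def _randomize_one(rates, rng, index=None, log10_lower=-3.0, log10_upper=3.0):
    mutant = np.array(rates, dtype=float)
    j = rng.integers(N_PARAM) if index is None else index
    mutant[j] = 10.0 ** rng.uniform(log10_lower, log10_upper)
    return mutant, j


def random_walk_population(circuit, founder, rng: np.random.Generator,
                           n_walks: int = 100, walk_length: int = 10,
                           retry_budget: int = 10_000) -> list[Individual]:
    """Viability-constrained random walk controls (n_walks x walk_length)."""
    founder = np.asarray(founder, dtype=float)
    controls: list[Individual] = []
    founder_id = -1
    for _ in range(n_walks):
        current = founder
        parent = founder_id
        for _ in range(walk_length):
            for attempt in range(retry_budget):
                candidate, _ = _randomize_one(current, rng)
                rec = circuit.evaluate(candidate)
                if rec.is_normal:
                    break
            else:
                raise RuntimeError("random-walk retry budget exhausted")
            ind = Individual(len(controls), parent, "control", candidate,
                             rec.U, rec.phenotype_class)
            controls.append(ind)
            current = candidate
            parent = ind.individual_id
    return controls


def derive_cases(circuit, controls: list[Individual], rng: np.random.Generator,
                 n_cases: int = 1000, attempt_budget: int = 1_000_000) -> list[Individual]:
    """Single-mutation diseased cases drawn (with replacement) from controls."""
    if not controls:
        raise ValueError("control collection is empty")
    cases: list[Individual] = []
    next_id = max(c.individual_id for c in controls) + 1
    attempts = 0
    while len(cases) < n_cases:
        if attempts >= attempt_budget:
            raise RuntimeError("case-derivation attempt budget exhausted")
        attempts += 1
        parent = controls[rng.integers(len(controls))]
        mutant, _ = _randomize_one(parent.rates, rng)
        rec = circuit.evaluate(mutant)
        if rec.is_diseased:
            cases.append(Individual(next_id, parent.individual_id, "case",
                                    mutant, rec.U, rec.phenotype_class))
            next_id += 1
    return cases


def build_pair(circuit, founder, rng: np.random.Generator, pair_id: int = 0,
               n_walks: int = 100, walk_length: int = 10,
               n_cases: int | None = None) -> PopulationPair:
    controls = random_walk_population(circuit, founder, rng, n_walks, walk_length)
    if n_cases is None:
        n_cases = len(controls)
    cases = derive_cases(circuit, controls, rng, n_cases)
    return PopulationPair(pair_id, np.asarray(founder, dtype=float), controls, cases)


def log10_wald_p(z: np.ndarray, df: float | None = None) -> np.ndarray:
    """log10 of the two-sided tail p-value for Wald statistics ``z``.

    Computed via the log survival function, so it is exact far into the
    tail (|z| of hundreds) where naive 2*(1-cdf) underflows.  ``df=None``
    uses the normal reference, otherwise Student's t with ``df`` degrees of
    freedom.
    """
    z = np.abs(np.asarray(z, dtype=float))
    if df is None:
        logsf = stats.norm.logsf(z)
    else:
        logsf = stats.t.logsf(z, df)
    return (np.log(2.0) + logsf) / _LN10


def _results_from_fit(beta, log10_p, flagged_mask) -> list[RegressionResult]:
    # rank by ascending p (log10_p); missing coefficients rank last,
    # ties broken by canonical order
    key = np.where(np.isnan(log10_p), np.inf, log10_p)
    order = np.lexsort((np.arange(N_PARAM), key))
    ranks = np.empty(N_PARAM, dtype=int)
    ranks[order] = np.arange(1, N_PARAM + 1)
    out = []
    for j in range(N_PARAM):
        p_ok = not np.isnan(log10_p[j])
        out.append(RegressionResult(
            parameter=PARAM_NAMES[j],
            beta=float(beta[j]),
            log10_p=float(log10_p[j]),
            rank=int(ranks[j]),
            significant=bool(p_ok and log10_p[j] <= np.log10(0.05)),
            flagged=bool(flagged_mask[j]),
        ))
    return out


def logistic_importance(pair: PopulationPair) -> list[RegressionResult]:
    """Joint multiple logistic regression of case/control status on the 15
    log10 rate constants; per-coefficient two-sided Wald p-values."""
    X, y, _ = pair.design()
    return _glm_importance(X, y, logistic=True)


def linear_importance(pair: PopulationPair) -> list[RegressionResult]:
    """Joint multiple linear regression of uptake U on the log10 rate
    constants; per-coefficient two-sided t-test p-values."""
    X, _, U = pair.design()
    return _glm_importance(X, U, logistic=False)


def _fit_logit(y, Xd):
    """Newton fit with an lbfgs + pseudo-inverse covariance fallback for
    (quasi-)separated designs.  Returns (params, bse, flagged)."""
    import statsmodels.api as sm
    import warnings as _warnings

    mod = sm.Logit(y, Xd)
    with _warnings.catch_warnings(), np.errstate(all="ignore"):
        _warnings.simplefilter("ignore")
        try:
            fit = mod.fit(disp=0, maxiter=200, method="newton")
            if (fit.mle_retvals.get("converged", False)
                    and np.all(np.isfinite(fit.bse))
                    and np.max(np.abs(fit.params)) < 30.0):
                return fit.params, fit.bse, False, None
        except Exception:
            pass
        # (quasi-)separation: the MLE diverges, Wald standard errors blow up
        # and the Wald z collapses (Hauck-Donner), so Wald p-values are
        # useless here.  Report instead the drop-one likelihood-ratio
        # p-value per coefficient — finite under separation — and flag the
        # result: these p-values are bounds, not Wald estimates.
        fit = mod.fit(disp=0, maxiter=1000, method="lbfgs")
        llf_full = fit.llf
        k = Xd.shape[1]
        log10_p = np.full(k, np.nan)
        for j in range(1, k):      # skip the intercept
            Xr = np.delete(Xd, j, axis=1)
            red = sm.Logit(y, Xr).fit(disp=0, maxiter=1000, method="lbfgs")
            lr = max(2.0 * (llf_full - red.llf), 0.0)
            log10_p[j] = stats.chi2.logsf(lr, 1) / _LN10
        return fit.params, None, True, log10_p


def _glm_importance(X, y, logistic: bool) -> list[RegressionResult]:
    import statsmodels.api as sm

    zero_var = np.ptp(X, axis=0) == 0
    keep = ~zero_var
    Xd = sm.add_constant(X[:, keep], has_constant="add")
    beta = np.full(N_PARAM, np.nan)
    log10_p = np.full(N_PARAM, np.nan)
    flagged = zero_var.copy()
    try:
        if logistic:
            params, bse, fit_flag, lrt_log10_p = _fit_logit(y, Xd)
            df = None
        else:
            fit = sm.OLS(y, Xd).fit()
            params, bse, fit_flag, lrt_log10_p = fit.params, fit.bse, False, None
            df = fit.df_resid
        beta[keep] = params[1:]
        if lrt_log10_p is not None:
            log10_p[keep] = lrt_log10_p[1:]
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                z = params[1:] / bse[1:]
            log10_p[keep] = log10_wald_p(z, df=df)
        if fit_flag or (bse is not None and not np.all(np.isfinite(bse))):
            flagged[:] = True
    except Exception:
        flagged[:] = True
    return _results_from_fit(beta, log10_p, flagged)


def variance_decomposition(pair: PopulationPair) -> VarianceDecomposition:
    """R² of the additive model vs additive + all 105 pairwise products of
    the log10 rate constants, on the continuous uptake."""
    X, _, U = pair.design()
    return _variance_decomposition_xy(X, U)


def _variance_decomposition_xy(X, y) -> VarianceDecomposition:
    import statsmodels.api as sm

    n, k = X.shape
    pairs = [X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k)]
    X_full = np.column_stack([X] + pairs)
    Xa = sm.add_constant(X, has_constant="add")
    Xf = sm.add_constant(X_full, has_constant="add")
    fit_a = sm.OLS(y, Xa).fit()            # pinv: minimum-norm if deficient
    fit_f = sm.OLS(y, Xf).fit()
    flagged = (np.linalg.matrix_rank(Xf) < Xf.shape[1])
    return VarianceDecomposition(float(fit_a.rsquared), float(fit_f.rsquared),
                                 flagged=bool(flagged))


def pair_study(circuit, founders: np.ndarray, rng: np.random.Generator,
               n_walks: int = 100, walk_length: int = 10,
               models: tuple = ("logistic", "linear"),
               with_decomposition: bool = False):
    """Regression importance across population pairs.

    ``founders`` is an (n_pairs, 15) array of normal-class genotypes (one
    fresh uniform viable draw per pair).  Returns a tidy DataFrame with one
    row per (pair, model, parameter), plus a list of VarianceDecomposition
    if requested.
    """
    founders = np.asarray(founders, dtype=float)
    if founders.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    rows = []
    decomps = []
    for pid, founder in enumerate(founders):
        pair = build_pair(circuit, founder, rng, pair_id=pid,
                          n_walks=n_walks, walk_length=walk_length)
        fits = {}
        if "logistic" in models:
            fits["logistic"] = logistic_importance(pair)
        if "linear" in models:
            fits["linear"] = linear_importance(pair)
        for model, results in fits.items():
            for r in results:
                rows.append({"pair_id": pid, "model": model,
                             "parameter": r.parameter, "beta": r.beta,
                             "log10_p": r.log10_p, "rank": r.rank,
                             "significant": r.significant,
                             "flagged": r.flagged})
        if with_decomposition:
            decomps.append(variance_decomposition(pair))
    df = pd.DataFrame(rows)
    return (df, decomps) if with_decomposition else df


def summarize_pair_study(df: pd.DataFrame, model: str = "logistic"):
    """Per-parameter aggregates across pairs: -log10 p span, fraction of
    pairs with p > 0.05, and rank histogram."""
    from .importance import rank_distribution

    sub = df[df["model"] == model]
    rows = []
    ranks = []
    for name in PARAM_NAMES:
        g = sub[sub["parameter"] == name]
        lp = -g["log10_p"].to_numpy()
        rows.append({
            "parameter": name,
            "neglog10p_min": np.nanmin(lp), "neglog10p_max": np.nanmax(lp),
            "neglog10p_span": np.nanmax(lp) - np.nanmin(lp),
            "frac_nonsignificant": float((~g["significant"]).mean()),
        })
    n_pairs = sub["pair_id"].nunique()
    rank_mat = (sub.pivot_table(index="pair_id", columns="parameter",
                                values="rank")
                .reindex(columns=list(PARAM_NAMES)).to_numpy())
    hist, ranges = rank_distribution(rank_mat)
    return pd.DataFrame(rows).set_index("parameter"), hist, ranges
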