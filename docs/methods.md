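# Methods

## Circuit model

The model is a 14-state mass-action ODE system for the core insulin
signaling cascade.  States are grouped into conserved pools: the IRS1 pool
(IRS1 + IRS1P + IRS1SP + IRS1P·PI3K = 1 nM), the PI3K pool
(PI3K + IRS1P·PI3K = 0.1 nM), the phospholipid pool
(PI345P3 + PI45P2 + PI34P2 = 100%), and the two kinase pairs
(Akt + AktP = 100%, PKCZ + PKCZP = 100%).  GLUT4 is not conserved — it is
synthesized at k14 = 0.11088 %/min and degraded at k₋14 = 0.001155 /min —
but its steady-state total is 100% by construction.  Two dimensionless
feedback strengths enter the IRS1 equations: f_AktP multiplies the
Akt-dependent return of IRS1P to IRS1 (positive feedback on signaling,
because active AktP depletes Akt), and f_PKCZP drives serine
phosphorylation of IRS1 into the inactive IRS1SP form (negative feedback).
The dephosphorylation constants of the two kinases are a single shared
value (kB_PKCZP serves both PKCZP equations).

Fifteen rate constants form the sampled genotype, in a fixed canonical
order (`causaldrift.PARAM_NAMES`).  The GLUT4 translocation block uses
published fixed constants only; the insulin-stimulated translocation rate
is linear in the weighted kinase activity, k13' = gain · k₋13 ·
(0.2·PKCZP + 0.8·AktP)/AP_eq with gain = (40/60) − (4/96) and
AP_eq = 9.09%.  This calibrates the membrane-localized fraction of GLUT4
to exactly 4% without stimulation and 40% when the weighted activity
equals AP_eq; both values are verified analytically (2×2 linear steady
state) and by long integration in the test suite.

## Input signal

The circuit input is the concentration of insulin-bound receptor.  The
upstream receptor-binding subsystem is not part of this package; a
piecewise-exponential surrogate stands in for it: zero before the pulse,
amplitude·(1 − exp(−t/τ_rise)) during the 15-minute pulse, and exponential
decay afterwards, continuous at the pulse end.  Defaults: amplitude
0.9 nM, τ_rise = 0.2 min (0.894 nM at one minute), τ_decay = 0.5 min.
A tabulated `(times, values)` trace can be plugged into `InsulinCircuit`
to replace the surrogate.

This is the one place where the package's trajectories are expected to
deviate quantitatively from a receptor-resolved model: under the
surrogate, the plateau kinase activation adapts to about 0.7 of the
maximal stimulation ratio and the reference genotype yields U ≈ 877 a.u.
rather than ≈ 1.17×10³.  The phenotype thresholds are fixed constants
(U₊ = 691.26, U₋ = 502.86), not derived from the reference uptake, and the
ensemble statistics that drive every analysis stage — viable volumes near
0.076 (normal) and 0.33 (diseased), their ratio, sensitivity and
robustness distributions — are insensitive to this offset.

## Integration and phenotype

Rate constants span six orders of magnitude, so the system is stiff;
trajectories are integrated with ODEPACK's LSODA (rtol 10⁻⁶, atol 10⁻⁹)
using a numba-compiled right-hand side and analytic Jacobian, sampled on a
uniform grid of Δt = 0.01 min over [0, 60] min.  U is the composite
trapezoid integral of membrane GLUT4 on that grid.  Integration failures
(step-budget exhaustion, non-finite states) are returned as flagged
records, excluded from viability counts and from f_del denominators, and
never raised.  The adaptive solution is cross-checked against an
independent fixed-step 4th-order Runge–Kutta oracle to a relative 10⁻⁴ in
U; the oracle's step is set by an explicit-stability bound on the fastest
linearized rate, so extremely stiff genotypes (bound below 2×10⁻⁵ min) are
outside its reach and are covered by the conservation and determinism
checks instead.

Classification: diseased iff U < U₋; normal iff U > U₊ *and* membrane
GLUT4 shows bona fide regulation — its maximum occurs strictly inside the
grid (maxima at the first or last grid point fail) and some later grid
value falls below half the maximum.  Everything else is intermediate.
The regulation clause applies only to the normal class.

## Sampling stage (the synthetic-data generator)

Genotypes are drawn as 10^x with x uniform per axis on (−3, 3); the open
interval needs no special handling since endpoints have measure zero.
Viable volumes are Monte-Carlo fractions with binomial standard error
√(V(1−V)/n); both classes are counted on one shared sample so their ratio
carries no between-sample noise.  The per-axis viability probability is
p = V^(1/15), the inversion of V = p¹⁵ for independent axes.  Marginal
summaries use 30 equal bins in log10 and box statistics with 1.5·IQR
whiskers; pairwise association is Spearman rank correlation.  Default
problem sizes: 2×10⁴ draws for volume estimates and 10⁶-attempt rejection
budgets, with a `full` preset mirroring the study-scale sizes (9.31×10⁵
draws, 2×10⁵ genotypes per class).  What the generator does *not* emulate:
any structure of real genetic variation — linkage, recombination,
diploidy, allele frequencies, or measurement noise.  Passing tests show
properties of the circuit's parameter space, not of human cohorts.

## Importance measures

Sensitivity uses a one-sided +10% perturbation, S = (ΔU/U)/(Δp/p), signed;
rankings use |S| with rank 1 for the largest magnitude and canonical-order
tie-breaking.  The +10% forward difference is a deliberate choice (the
direction is not intrinsic to the definition); unit tests verify agreement
with a central-difference oracle at smaller steps.  f_del re-randomizes
the focal constant n times over the full range and counts diseased
outcomes; for f_del rankings every parameter tied at f_del = 0 receives
the lowest possible rank of 15.  |S| = 0 is floored at 10⁻³⁰⁰ for log
displays.

## Case-control populations

Controls: 100 restarted random walks of length 10 from a normal-class
founder; each step re-randomizes one uniformly chosen constant and retries
until the result is normal, so walk step k differs from the founder in at
most k constants.  Cases: repeatedly pick a random control (with
replacement), re-randomize one random constant, keep iff diseased.  Every
case is one mutation from its recorded parent.

Predictors for the regressions are log10 of the rate constants —
sampling and mutation act in log space, making it the natural genotype
coordinate — unstandardized.  Case/control status (1/0) is regressed on
all 15 predictors jointly by maximum-likelihood logistic regression
(statsmodels); p-values are two-sided Wald tests computed via the log
survival function, so they are exact far into the tail (p ≈ 10⁻¹⁵⁰ poses
no difficulty).  No multiple-testing correction is applied; ranks and the
p > 0.05 cutoff use raw p-values.  When a design is (quasi-)separated the
Wald statistic degenerates (the Hauck–Donner effect: diverging
coefficients, collapsing z), so the fit is flagged and each coefficient's
p-value is replaced by its drop-one likelihood-ratio p-value, which
remains finite and serves as a bound rather than a Wald estimate.
Separation is common at the reduced default scale (pairs of 200+200) and
rare at full scale (1000+1000).  Linear regression on the continuous U
uses OLS with t-test p-values in log space; the epistasis decomposition
compares the additive R² with the R² after adding all 105 pairwise
products (pinv-based fit, flagged if rank-deficient).

## Evolutionary simulation

A population of N = 100 copies of a viable founder evolves for 500
generations: every individual has exactly one uniformly chosen constant
re-randomized, then the next generation is resampled with replacement from
the viable (normal-class) mutants — equivalently, uniformly from the
viable subset.  If no mutant is viable the pre-mutation population is
carried over and the generation recorded.  Each generation the sensitivity
profile is evaluated at a representative genotype.  Two modes are
implemented: `tracked` (default) evaluates the individual at a fixed
population index, which turns over with the population every generation;
`mean` evaluates the component-wise geometric mean of the population.
The mean genotype averages over N lineages and therefore decorrelates
roughly twofold slower than the population itself; measured over
500-generation runs it yields mean decay times near 13 generations versus
near 7 for the tracked individual, and the tracked mode was made the
default as the closer operationalization of per-generation importance in
an evolving population.

Drift statistics: the lag-τ autocorrelation of log₁₀|S| per parameter
(mean-subtracted, normalized by the overall sample variance, lags 0..50)
and the decay time — the smallest τ ≥ 2 with ρ(τ) < ρ(1)/2, censored at
the last lag if never crossed (censored values are excluded from means and
flagged).  Given the one-generation sampling interval, 2 is the smallest
decay time the estimator can report.

## Numerical and design notes

* Determinism: every stochastic routine takes a seeded
  `numpy.random.Generator` or a seed in its config; artifacts embed their
  seed and stage manifests record sizes and integration counts.
* Problem sizes: the default (`desk`) preset uses 2×10⁴ volume draws,
  10³ genotypes per class, 200 importance sets × 30 mutations, 10
  population pairs of 200+200 and one 500-generation evolution run; the
  `full` preset restores the study-scale sizes (9.31×10⁵ draws, 2×10⁵
  per class, 1000 sets × 100 mutations, 100 pairs of 1000+1000).  Reduced
  sizes widen Monte-Carlo error but leave every qualitative contrast
  intact except the extreme p-value spans, which compress with population
  size (log p scales roughly linearly in n).
* Rank ties are broken by canonical parameter order, making repeated
  rankings of identical records identical.
* CSV artifacts round-trip byte-exactly through
  `causaldrift.io.read_artifact_csv`.

## Known limitations

* The surrogate input signal underestimates plateau activation relative
  to a receptor-resolved model (U_ref ≈ 877 vs ≈ 1.17×10³ a.u.); only
  analyses anchored to the absolute reference uptake are affected.
* Wald p-values from separated logistic fits are bounds, not estimates.
* The fixed-step oracle cannot validate the stiffest genotypes
  (explicit-stability limit); those rely on the adaptive solver's own
  tolerances plus conservation checks.
* The mutation model is one-parameter-at-a-time full-range randomization;
  no small-effect mutation spectrum is modeled.
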