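# causaldrift

Mutational robustness can hide the genetic determinants of a complex
disease: in a signaling circuit whose output is robust to parameter
change, the *identity* of the parameters that matter shifts from one
genetic background to the next.  `causaldrift` reproduces this analysis
end to end for a simplified insulin-signaling circuit implicated in type 2
diabetes, for researchers in systems biology and quantitative genetics who
want to simulate, sample and re-analyze the phenomenon.

## The model

A 14-state mass-action ODE system tracks the core events downstream of the
insulin receptor: IRS1 tyrosine/serine phosphorylation (with positive
feedback from AktP and negative feedback from PKCZP), formation of the
IRS1P·PI3K complex, interconversion of the phospholipids
PI45P2 / PI345P3 / PI34P2, phosphorylation of the kinases Akt and PKC-ζ,
and translocation of the glucose transporter GLUT4 between an internal pool
and the plasma membrane.  Fifteen rate constants — the circuit's
"genotype" — are genetically determined and sampled log-uniformly over
(10⁻³, 10³); the GLUT4 translocation constants are fixed at their
published values, with the insulin-stimulated rate

    k13' = [(40/60) − (4/96)] · k₋13 · (0.2·[PKCZP] + 0.8·[AktP]) / AP_eq

calibrated so 4% of GLUT4 is membrane-localized at rest and 40% at maximal
stimulation.  The scalar phenotype is the glucose-uptake proxy

    U = ∫₀⁶⁰ [GLUT4_mem](t) dt   (a.u.)

after a 15-minute insulin pulse.  A genotype is **normal** if
U > 691.26 and membrane GLUT4 shows bona fide regulation (peaks inside the
window, then falls below half its maximum), **diseased** if U < 502.86.

On top of the circuit, the package implements four importance measures per
genetic background and the population analyses built from them:

* sensitivity coefficients S = (ΔU/U)/(Δp/p) and their |S| ranks,
* f_del, the fraction of full-range randomizations of one parameter that
  push U below the disease threshold,
* Wald p-values from joint multiple logistic regression in simulated
  case-control population pairs (1000 related controls built by a
  viability-constrained random walk + 1000 single-mutation cases),
* linear-regression p-values and an additive vs pairwise-epistasis R²
  decomposition,

plus Monte-Carlo viable-volume estimation and a 500-generation
mutation–selection simulation (N = 100, stabilizing selection for the
normal phenotype) with autocorrelation decay times of log₁₀|S|.

## Worked example

```python
from causaldrift import InsulinCircuit, reference_parameters
from causaldrift.importance import sensitivity_profile

circuit = InsulinCircuit()
rec = circuit.evaluate(reference_parameters())
print(f"U = {rec.U:.1f} a.u., class = {rec.phenotype_class}, "
      f"peak at t = {rec.t_max:.2f} min")
for r in sensitivity_profile(circuit, reference_parameters())[:4]:
    print(f"{r.parameter:>14s}  S = {r.S:+.4f}  rank {r.rank}")
```

prints

```
U = 876.5 a.u., class = normal, peak at t = 11.68 min
      kF_IRS1P  S = +0.1542  rank 9
      kB_IRS1P  S = -0.2214  rank 8
     kB_IRS1SP  S = +0.0746  rank 11
 kF_IRS1P_PI3K  S = +0.3394  rank 5
```

The reference genotype is classified normal; its uptake sits above the
normal threshold, and the sensitivity profile shows sloppy control — the
four constants shown already differ several-fold in their effect on U, and
across the full profile |S| spans orders of magnitude.  (The uptake value
depends on the surrogate input-signal shape; see `docs/methods.md`.)

The pipeline stages are also exposed on the command line:

```sh
causaldrift volume --seed 1 --scale desk --out results/
causaldrift evolve --seed 1 --scale desk --out results/
causaldrift report --out results/
```

Each stage writes CSV/JSON artifacts plus a manifest recording the seed,
package version, wall-clock time and integration counts.

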