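"""Core insulin-signaling circuit: ODE model, glucose-uptake phenotype,
and normal/diseased/intermediate classification.

The circuit tracks insulin-receptor-substrate phosphorylation, PI3K complex
formation, phospholipid second messengers, the kinases Akt and PKC-zeta, and
translocation of the glucose transporter GLUT4 to the plasma membrane.  Its
scalar phenotype is the glucose uptake proxy

    U = integral over [0, 60] min of [GLUT4_mem](t) dt   (a.u.)

A genotype (15 sampled rate constants) is *normal* if U exceeds ``U_plus``
and membrane GLUT4 shows bona fide regulation (rises, peaks strictly inside
the window, then falls below half its maximum), and *diseased* if U falls
below ``U_minus``; anything else is *intermediate*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.integrate import odeint

from . import _kernel
from ._kernel import N_PARAM, N_STATE

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "RateParameters",
    "FixedConstants",
    "SignalConfig",
    "PhenotypeConfig",
    "SolverConfig",
    "Trajectory",
    "PhenotypeRecord",
    "InsulinCircuit",
    "input_signal",
    "glut4_rate",
    "reference_parameters",
    "initial_state",
]

#: Canonical order of the 15 sampled rate constants (the circuit "genotype").
PARAM_NAMES = (
    "kF_IRS1P", "kB_IRS1P", "kB_IRS1SP", "kF_IRS1P_PI3K", "kB_IRS1P_PI3K",
    "kF_PI45P2", "kB_PI45P2", "kF_PI34P2", "kB_PI34P2",
    "kF_AktP", "kB_AktP", "kF_PKCZP", "kB_PKCZP",
    "f_AktP", "f_PKCZP",
)

STATE_NAMES = (
    "IRS1", "IRS1P", "IRS1SP", "PI3K", "IRS1P_PI3K",
    "PI345P3", "PI45P2", "PI34P2", "Akt", "AktP",
    "PKCZ", "PKCZP", "GLUT4_int", "GLUT4_mem",
)

#: Published reference values of the sampled constants (canonical order).
_REFERENCE_VALUES = (
    10.0,    # kF_IRS1P      [1/min/nM]
    5.0,     # kB_IRS1P      [1/min]
    0.1,     # kB_IRS1SP     [1/min]
    0.706,   # kF_IRS1P_PI3K [1/min/nM]
    10.0,    # kB_IRS1P_PI3K [1/min]
    300.0,   # kF_PI45P2     [1/min/nM]
    42.15,   # kB_PI45P2     [1/min]
    2.96,    # kF_PI34P2     [1/min]
    2.77,    # kB_PI34P2     [1/min]
    0.21,    # kF_AktP       [1/min]
    6.93,    # kB_AktP       [1/min]
    0.21,    # kF_PKCZP      [1/min]
    6.93,    # kB_PKCZP      [1/min]
    0.001,   # f_AktP        [-]
    0.3,     # f_PKCZP       [-]
)

#: Pre-stimulation state: phosphorylated species negligible, phospholipid
#: pool almost entirely PI45P2, 4% of GLUT4 at the membrane.
_INITIAL_STATE = (
    1.0, 0.0, 0.0, 0.1, 0.0,          # IRS1 pool [nM], PI3K pool [nM]
    0.31, 99.4, 0.29,                 # phospholipids [%]
    100.0, 0.0, 100.0, 0.0,           # Akt, PKCZ pairs [%]
    96.0, 4.0,                        # GLUT4 [%]
)


@dataclass(frozen=True)
class RateParameters:
    """The 15 genetically determined rate constants, in canonical order."""

    kF_IRS1P: float = 10.0
    kB_IRS1P: float = 5.0
    kB_IRS1SP: float = 0.1
    kF_IRS1P_PI3K: float = 0.706
    kB_IRS1P_PI3K: float = 10.0
    kF_PI45P2: float = 300.0
    kB_PI45P2: float = 42.15
    kF_PI34P2: float = 2.96
    kB_PI34P2: float = 2.77
    kF_AktP: float = 0.21
    kB_AktP: float = 6.93
    kF_PKCZP: float = 0.21
    kB_PKCZP: float = 6.93
    f_AktP: float = 0.001
    f_PKCZP: float = 0.3

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"rate constant {f.name} must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, values) -> "RateParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_PARAM,):
            raise ValueError(f"expected {N_PARAM} rate constants, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))


def reference_parameters() -> np.ndarray:
    """Published reference rate constants as a canonical-order array."""
    return np.array(_REFERENCE_VALUES)


def initial_state() -> np.ndarray:
    return np.array(_INITIAL_STATE)


@dataclass(frozen=True)
class FixedConstants:
    """GLUT4 translocation constants that are not subject to sampling.

    ``translocation_gain`` scales the insulin-stimulated rate so that at
    maximal stimulation 40% (instead of the basal 4%) of GLUT4 is
    membrane-localized.
    """

    k13: float = 0.006958          # basal translocation [1/min]
    k_minus13: float = 0.167       # internalization [1/min]
    k14: float = 0.11088           # synthesis [%/min]
    k_minus14: float = 0.001155    # degradation [1/min]
    AP_eq: float = 9.09            # 0.2*PKCZP + 0.8*AktP at max stimulation [%]
    translocation_gain: float = (40.0 / 60.0) - (4.0 / 96.0)

    def to_array(self) -> np.ndarray:
        return np.array([self.k13, self.k_minus13, self.k14, self.k_minus14,
                         self.AP_eq, self.translocation_gain])


@dataclass(frozen=True)
class SignalConfig:
    """Surrogate for insulin-bound receptor after a 15-minute insulin pulse:
    fast exponential rise to ~0.9 nM, plateau, fast decay after removal."""

    amplitude: float = 0.9     # [nM]
    pulse_start: float = 0.0   # [min]
    pulse_end: float = 15.0    # [min]
    tau_rise: float = 0.2      # [min]
    tau_decay: float = 0.5     # [min]

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.pulse_start >= self.pulse_end:
            raise ValueError("pulse_start must precede pulse_end")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([self.amplitude, self.pulse_start, self.pulse_end,
                         self.tau_rise, self.tau_decay])


@dataclass(frozen=True)
class PhenotypeConfig:
    """Uptake thresholds and the bona fide regulation rule."""

    U_plus: float = 691.26            # minimum normal uptake [a.u.]
    U_minus: float = 502.86           # maximum diseased uptake [a.u.]
    horizon: float = 60.0             # integration window [min]
    regulation_fraction: float = 0.5  # post-peak drop required for "normal"

    def __post_init__(self):
        if self.U_minus >= self.U_plus:
            raise ValueError("U_minus must be below U_plus")


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-6
    atol: float = 1e-9
    dt_output: float = 0.01   # [min] uniform output grid for U and regulation
    max_steps: int = 20000


@dataclass
class Trajectory:
    """Dense-grid solution of the 14 circuit states over [0, horizon]."""

    times: np.ndarray           # (n,)
    states: np.ndarray          # (n, 14), columns in STATE_NAMES order
    success: bool = True
    message: str = ""

    @property
    def glut4_mem(self) -> np.ndarray:
        return self.states[:, 13]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time", self.times)
        return df


@dataclass
class PhenotypeRecord:
    U: float
    phenotype_class: str        # "normal" | "diseased" | "intermediate"
    t_max: float
    regulation_ok: bool
    failed: bool = False

    @property
    def is_normal(self) -> bool:
        return self.phenotype_class == "normal"

    @property
    def is_diseased(self) -> bool:
        return self.phenotype_class == "diseased"


def input_signal(t, cfg: SignalConfig | None = None):
    """Insulin-bound receptor concentration [nM] at time ``t`` [min].

    Piecewise-exponential pulse surrogate; accepts scalars or arrays.
    """
    cfg = cfg or SignalConfig()
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    sig = cfg.to_array()
    if t_arr.ndim == 0:
        return _kernel.signal_value(float(t_arr), sig)
    return np.array([_kernel.signal_value(ti, sig) for ti in t_arr.ravel()]).reshape(t_arr.shape)


def glut4_rate(AktP, PKCZP, fixed: FixedConstants | None = None):
    """Insulin-stimulated GLUT4 translocation rate k13' [1/min]."""
    fixed = fixed or FixedConstants()
    if fixed.AP_eq == 0:
        raise ValueError("AP_eq must be nonzero")
    return fixed.translocation_gain * fixed.k_minus13 * (0.2 * PKCZP + 0.8 * AktP) / fixed.AP_eq


def _coerce_params(rates) -> np.ndarray:
    if isinstance(rates, RateParameters):
        return rates.to_array()
    arr = np.asarray(rates, dtype=float)
    if arr.shape != (N_PARAM,):
        raise ValueError(f"expected {N_PARAM} rate constants, got shape {arr.shape}")
    return arr


class InsulinCircuit:
    """The simplified insulin-signaling circuit with fixed configuration.

    Bundles the non-sampled constants, input-signal shape, phenotype
    thresholds and solver settings, and evaluates genotypes (15-vectors of
    rate constants) to trajectories and phenotype records.

    Parameters
    ----------
    fixed, signal, phenotype, solver
        Configuration blocks; defaults reproduce the published setup.
    signal_trace
        Optional ``(times, values)`` tabulated input signal that replaces the
        built-in surrogate (linearly interpolated, zero outside its support).
    """

    def __init__(self, fixed: FixedConstants | None = None,
                 signal: SignalConfig | None = None,
                 phenotype: PhenotypeConfig | None = None,
                 solver: SolverConfig | None = None,
                 signal_trace: tuple | None = None):
        self.fixed = fixed or FixedConstants()
        self.signal = signal or SignalConfig()
        self.phenotype_cfg = phenotype or PhenotypeConfig()
        self.solver = solver or SolverConfig()
        self.signal_trace = signal_trace
        if self.fixed.AP_eq == 0:
            raise ValueError("AP_eq must be nonzero")
        n_out = int(round(self.phenotype_cfg.horizon / self.solver.dt_output)) + 1
        self._grid = np.linspace(0.0, self.phenotype_cfg.horizon, n_out)
        self._fixed_arr = self.fixed.to_array()
        self._sig_arr = self.signal.to_array()
        self.n_integrations = 0

    # -- dynamics ----------------------------------------------------------

    def derivatives(self, t: float, state, rates) -> np.ndarray:
        """Time derivative of the 14 circuit states at time ``t`` [min]."""
        y = np.asarray(state, dtype=float)
        p = _coerce_params(rates)
        if self.signal_trace is not None:
            s = self._interp_signal(t)
            sig = np.array([0.0, np.inf, np.inf, 1.0, 1.0])
            dy = _kernel.rhs(y, 0.0, p, self._fixed_arr, sig)
            # re-add signal-dependent terms removed by the zero-amplitude call
            r1 = p[0] * y[0] * s
            dy[0] -= r1
            dy[1] += r1
            return dy
        return _kernel.rhs(y, float(t), p, self._fixed_arr, self._sig_arr)

    def _interp_signal(self, t):
        ts, vs = self.signal_trace
        return float(np.interp(t, ts, vs, left=0.0, right=0.0))

    def simulate(self, rates, y0=None) -> Trajectory:
        """Integrate the circuit over [0, horizon] on the dense output grid.

        Integration failures are returned as a flagged ``Trajectory`` with
        ``success=False`` rather than raised.
        """
        p = _coerce_params(rates)
        y0 = initial_state() if y0 is None else np.asarray(y0, dtype=float)
        self.n_integrations += 1
        if self.signal_trace is not None:
            return self._simulate_generic(p, y0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, info = odeint(
                _kernel.rhs, y0, self._grid,
                args=(p, self._fixed_arr, self._sig_arr),
                Dfun=_kernel.jacobian,
                rtol=self.solver.rtol, atol=self.solver.atol,
                mxstep=self.solver.max_steps,
                full_output=True, printmessg=False,
            )
        ok = info["message"] == "Integration successful." and np.all(np.isfinite(out))
        return Trajectory(self._grid, out, success=bool(ok), message=str(info["message"]))

    def _simulate_generic(self, p, y0):
        # slower fallback path used when a tabulated signal trace is plugged in
        from scipy.integrate import solve_ivp
        sol = solve_ivp(
            lambda t, y: self.derivatives(t, y, p), (0.0, self._grid[-1]), y0,
            method="LSODA", t_eval=self._grid,
            rtol=self.solver.rtol, atol=self.solver.atol,
        )
        ok = sol.success and np.all(np.isfinite(sol.y))
        states = sol.y.T if ok else np.full((len(self._grid), N_STATE), np.nan)
        return Trajectory(self._grid, states, success=bool(ok), message=sol.message)

    # -- phenotype ---------------------------------------------------------

    def uptake(self, traj: Trajectory) -> float:
        """Glucose-uptake proxy U: trapezoidal integral of membrane GLUT4."""
        horizon = self.phenotype_cfg.horizon
        if traj.times[-1] < horizon - 1e-9:
            raise ValueError("trajectory does not cover the uptake horizon")
        mask = traj.times <= horizon + 1e-12
        return float(np.trapezoid(traj.glut4_mem[mask], traj.times[mask]))

    def classify(self, traj: Trajectory, U: float | None = None) -> PhenotypeRecord:
        """Assign normal/diseased/intermediate and the regulation flag.

        Regulation requires the membrane-GLUT4 maximum to occur strictly
        inside (0, horizon) and the curve to later drop below
        ``regulation_fraction`` times that maximum.
        """
        if not traj.success:
            return PhenotypeRecord(np.nan, "failed", np.nan, False, failed=True)
        if U is None:
            U = self.uptake(traj)
        cfg = self.phenotype_cfg
        g = traj.glut4_mem
        i_max = int(np.argmax(g))
        t_max = float(traj.times[i_max])
        regulation_ok = False
        if 0 < i_max < len(g) - 1:
            regulation_ok = bool(np.any(g[i_max + 1:] < cfg.regulation_fraction * g[i_max]))
        if U < cfg.U_minus:
            cls = "diseased"
        elif U > cfg.U_plus and regulation_ok:
            cls = "normal"
        else:
            cls = "intermediate"
        return PhenotypeRecord(float(U), cls, t_max, regulation_ok)

    def evaluate(self, rates) -> PhenotypeRecord:
        """Simulate a genotype and classify its uptake phenotype."""
        traj = self.simulate(rates)
        return self.classify(traj)
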