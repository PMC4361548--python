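"""Uniform log-domain sampling of the 15-dimensional rate-constant space.

Each genotype is drawn by sampling 15 independent exponents x uniformly on
(log10_lower, log10_upper) — the published range is (-3, 3) — and setting
the rate constant to 10**x.  Viable volumes are the Monte-Carlo fraction of
draws whose phenotype matches a target class, with the binomial standard
error sqrt(V(1-V)/n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._kernel import N_PARAM
from .model import PARAM_NAMES

__all__ = [
    "SamplingConfig",
    "VolumeEstimate",
    "sample_vector",
    "binomial_se",
    "estimate_volume",
    "estimate_volumes",
    "per_axis_probability",
    "sample_viable",
    "marginal_summaries",
    "pairwise_associations",
]


@dataclass(frozen=True)
class SamplingConfig:
    log10_lower: float = -3.0
    log10_upper: float = 3.0
    n_samples: int = 10_000
    seed: int = 0
    target_class: str = "normal"

    def __post_init__(self):
        if self.log10_lower >= self.log10_upper:
            raise ValueError("log10_lower must be below log10_upper")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.target_class not in ("normal", "diseased"):
            raise ValueError("target_class must be 'normal' or 'diseased'")


@dataclass(frozen=True)
class VolumeEstimate:
    """Monte-Carlo estimate of a fractional parameter-space volume."""

    V: float
    SE: float
    n: int
    n_hits: int
    target_class: str = "normal"


def sample_vector(rng: np.random.Generator, log10_lower: float = -3.0,
                  log10_upper: float = 3.0) -> np.ndarray:
    """Draw one genotype: 15 rate constants, log-uniform on the range."""
    return 10.0 ** rng.uniform(log10_lower, log10_upper, N_PARAM)


def binomial_se(V: float, n: int) -> float:
    """Normal-approximation standard error of a binomial fraction."""
    return float(np.sqrt(V * (1.0 - V) / n))


def _classify_sample(circuit, cfg: SamplingConfig):
    """Classify cfg.n_samples fresh uniform draws; returns class labels and
    the sampled matrix (n, 15)."""
    rng = np.random.default_rng(cfg.seed)
    mat = np.empty((cfg.n_samples, N_PARAM))
    labels = np.empty(cfg.n_samples, dtype=object)
    for i in range(cfg.n_samples):
        mat[i] = sample_vector(rng, cfg.log10_lower, cfg.log10_upper)
        labels[i] = circuit.evaluate(mat[i]).phenotype_class
    return labels, mat


def estimate_volume(circuit, cfg: SamplingConfig) -> VolumeEstimate:
    """Fraction of uniform draws whose phenotype matches ``cfg.target_class``.

    Failed integrations count toward the denominator but never as hits.
    """
    labels, _ = _classify_sample(circuit, cfg)
    return _volume_from_labels(labels, cfg.target_class)


def estimate_volumes(circuit, cfg: SamplingConfig) -> dict[str, VolumeEstimate]:
    """Normal- and diseased-class volumes from one shared sample, so that
    their ratio carries no between-sample noise."""
    labels, _ = _classify_sample(circuit, cfg)
    return {cls: _volume_from_labels(labels, cls) for cls in ("normal", "diseased")}


def _volume_from_labels(labels, target_class) -> VolumeEstimate:
    n = len(labels)
    n_hits = int(np.sum(labels == target_class))
    V = n_hits / n
    return VolumeEstimate(V=V, SE=binomial_se(V, n), n=n, n_hits=n_hits,
                          target_class=target_class)


def per_axis_probability(V: float) -> float:
    """Per-axis viability probability p with V = p**15, i.e. p = V**(1/15)."""
    if V <= 0:
        raise ValueError("V must be positive")
    return float(V ** (1.0 / N_PARAM))


def sample_viable(circuit, n: int, cfg: SamplingConfig,
                  max_attempts: int = 1_000_000):
    """Rejection-sample ``n`` genotypes of the target class.

    Returns ``(params, records, attempts)`` where ``params`` is an (n, 15)
    array and ``records`` the matching phenotype records.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(cfg.seed)
    out = np.empty((n, N_PARAM))
    records = []
    attempts = 0
    while len(records) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"rejection budget of {max_attempts} attempts exhausted "
                f"({len(records)}/{n} {cfg.target_class} genotypes found)")
        p = sample_vector(rng, cfg.log10_lower, cfg.log10_upper)
        attempts += 1
        rec = circuit.evaluate(p)
        if rec.phenotype_class == cfg.target_class:
            out[len(records)] = p
            records.append(rec)
    return out, records, attempts


def marginal_summaries(params: np.ndarray, n_bins: int = 30,
                       log10_lower: float = -3.0, log10_upper: float = 3.0):
    """Per-parameter log10-domain histograms and box-plot statistics.

    Returns a dict with histogram edges, per-parameter normalized masses,
    and a DataFrame of median/quartiles/whiskers (1.5 IQR rule).
    """
    import pandas as pd

    if params.shape[0] == 0:
        raise ValueError("empty collection")
    logp = np.log10(params)
    edges = np.linspace(log10_lower, log10_upper, n_bins + 1)
    masses = np.empty((N_PARAM, n_bins))
    rows = []
    for j, name in enumerate(PARAM_NAMES):
        counts, _ = np.histogram(logp[:, j], bins=edges)
        masses[j] = counts / counts.sum()
        q25, med, q75 = np.percentile(logp[:, j], [25, 50, 75])
        iqr = q75 - q25
        rows.append({
            "parameter": name, "median": med, "q25": q25, "q75": q75,
            "whisker_lo": q25 - 1.5 * iqr, "whisker_hi": q75 + 1.5 * iqr,
            "min": logp[:, j].min(), "max": logp[:, j].max(),
        })
    return {"edges": edges, "masses": masses,
            "box_stats": pd.DataFrame(rows).set_index("parameter")}


def pairwise_associations(normal_params: np.ndarray,
                          diseased_params: np.ndarray) -> dict[str, np.ndarray]:
    """Spearman rank-correlation matrices (15 x 15) for both classes.

    A constant column yields NaN entries for its pairs.
    """
    out = {}
    for cls, mat in (("normal", normal_params), ("diseased", diseased_params)):
        if mat.shape[0] < 100:
            raise ValueError(f"{cls} collection needs >= 100 members")
        with np.errstate(invalid="ignore"):
            R = stats.spearmanr(np.log10(mat)).statistic
        const = np.ptp(mat, axis=0) == 0
        R[const, :] = np.nan
        R[:, const] = np.nan
        np.fill_diagonal(R, np.where(const, np.nan, 1.0))
        out[cls] = R
    return out
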