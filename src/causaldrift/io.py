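"""Run configuration, artifact serialization, and stage orchestration.

Artifacts are plain CSV/JSON with the canonical parameter order enforced;
every stochastic artifact embeds the seed that produced it, and each stage
writes a small manifest (seed, version, wall-clock, counters) next to its
outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import (InsulinCircuit, PARAM_NAMES, PhenotypeConfig, SignalConfig,
                    SolverConfig)
from .sampling import SamplingConfig

__all__ = ["RunConfig", "load_config", "run_stage", "read_artifact_csv",
           "SCALE_PRESETS"]

#: Stage problem sizes.  ``full`` mirrors the published study; ``desk``
#: is the reduced configuration used for routine runs.
SCALE_PRESETS = {
    "full": dict(volume_n=931_000, sample_n=200_000, importance_sets=1000,
                 importance_mutations=100, n_pairs=100, n_walks=100,
                 walk_length=10, evo_N=100, evo_generations=500),
    "desk": dict(volume_n=20_000, sample_n=1000, importance_sets=200,
                 importance_mutations=30, n_pairs=10, n_walks=20,
                 walk_length=10, evo_N=100, evo_generations=500),
}

STAGES = ("volume", "sample", "importance", "casecontrol", "evolve", "report")


@dataclass
class RunConfig:
    seed: int = 0
    scale: str = "desk"
    out_dir: str = "causaldrift_out"
    overrides: dict = field(default_factory=dict)   # per-stage size overrides
    solver: dict = field(default_factory=dict)
    signal: dict = field(default_factory=dict)
    phenotype: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"unknown scale preset {self.scale!r}")

    def sizes(self) -> dict:
        s = dict(SCALE_PRESETS[self.scale])
        s.update(self.overrides)
        return s

    def circuit(self) -> InsulinCircuit:
        return InsulinCircuit(
            signal=SignalConfig(**self.signal),
            phenotype=PhenotypeConfig(**self.phenotype),
            solver=SolverConfig(**self.solver),
        )


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON — YAML is a superset) run configuration."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"malformed config file {path}")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def read_artifact_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV with bit-exact float parsing, so that
    write -> read -> write reproduces the file byte for byte."""
    return pd.read_csv(path, float_precision="round_trip")


def _param_frame(mat: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(mat, columns=list(PARAM_NAMES))


def _write_manifest(out: Path, stage: str, cfg: RunConfig, t0: float,
                    counters: dict):
    manifest = {
        "stage": stage, "seed": cfg.seed, "scale": cfg.scale,
        "version": __version__, "wall_clock_s": round(time.time() - t0, 3),
        **counters,
    }
    (out / f"{stage}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_stage(stage: str, cfg: RunConfig) -> dict:
    """Execute one pipeline stage and write its artifacts.

    Returns the stage manifest.  Unknown stages raise ValueError.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    circuit = cfg.circuit()
    sizes = cfg.sizes()
    runner = globals()[f"_stage_{stage}"]
    counters = runner(circuit, cfg, sizes, out)
    return _write_manifest(out, stage, cfg, t0, counters)


def _stage_volume(circuit, cfg, sizes, out):
    from .sampling import estimate_volumes, per_axis_probability

    scfg = SamplingConfig(n_samples=sizes["volume_n"], seed=cfg.seed)
    vols = estimate_volumes(circuit, scfg)
    payload = {
        cls: {"class": cls, "V": v.V, "SE": v.SE, "n": v.n,
              "n_hits": v.n_hits, "per_axis_p": per_axis_probability(v.V)
              if v.V > 0 else None, "seed": cfg.seed}
        for cls, v in vols.items()
    }
    payload["ratio_diseased_over_normal"] = (
        vols["diseased"].V / vols["normal"].V if vols["normal"].V > 0 else None)
    (out / "volumes.json").write_text(json.dumps(payload, indent=2))
    return {"n_samples": sizes["volume_n"],
            "n_integrations": circuit.n_integrations}


def _stage_sample(circuit, cfg, sizes, out):
    from .sampling import marginal_summaries, pairwise_associations, sample_viable

    frames = []
    mats = {}
    for i, cls in enumerate(("normal", "diseased")):
        scfg = SamplingConfig(n_samples=1, seed=cfg.seed + i, target_class=cls)
        mat, records, attempts = sample_viable(circuit, sizes["sample_n"], scfg,
                                               max_attempts=10_000_000)
        mats[cls] = mat
        df = _param_frame(mat)
        df.insert(0, "set_id", np.arange(len(mat)))
        df.insert(1, "class", cls)
        df.insert(2, "U", [r.U for r in records])
        df.insert(3, "regulation_ok", [r.regulation_ok for r in records])
        frames.append(df)
    pd.concat(frames).to_csv(out / "parameter_sets.csv", index=False)

    summaries = {cls: marginal_summaries(mats[cls]) for cls in mats}
    box = pd.concat({cls: s["box_stats"] for cls, s in summaries.items()},
                    names=["class"])
    box.to_csv(out / "marginal_box_stats.csv")
    if all(len(m) >= 100 for m in mats.values()):
        assoc = pairwise_associations(mats["normal"], mats["diseased"])
        np.savetxt(out / "spearman_normal.csv", assoc["normal"], delimiter=",")
        np.savetxt(out / "spearman_diseased.csv", assoc["diseased"], delimiter=",")
    return {"n_per_class": sizes["sample_n"],
            "n_integrations": circuit.n_integrations}


def _stage_importance(circuit, cfg, sizes, out):
    from .importance import importance_study
    from .sampling import sample_viable

    scfg = SamplingConfig(n_samples=1, seed=cfg.seed, target_class="normal")
    mat, _, _ = sample_viable(circuit, sizes["importance_sets"], scfg,
                              max_attempts=10_000_000)
    rng = np.random.default_rng(cfg.seed + 1)
    df = importance_study(circuit, mat, rng,
                          n_mutations=sizes["importance_mutations"])
    df.to_csv(out / "importance.csv", index=False)
    return {"n_sets": sizes["importance_sets"],
            "n_mutations": sizes["importance_mutations"],
            "n_integrations": circuit.n_integrations}


def _stage_casecontrol(circuit, cfg, sizes, out):
    from .populations import pair_study
    from .sampling import sample_viable

    scfg = SamplingConfig(n_samples=1, seed=cfg.seed, target_class="normal")
    founders, _, _ = sample_viable(circuit, sizes["n_pairs"], scfg,
                                   max_attempts=10_000_000)
    rng = np.random.default_rng(cfg.seed + 1)
    df, decomps = pair_study(circuit, founders, rng, n_walks=sizes["n_walks"],
                             walk_length=sizes["walk_length"],
                             with_decomposition=True)
    df.to_csv(out / "regression.csv", index=False)
    pd.DataFrame([{"pair_id": i, "R2_additive": d.R2_additive,
                   "R2_with_pairwise": d.R2_with_pairwise,
                   "delta_R2": d.delta_R2, "flagged": d.flagged}
                  for i, d in enumerate(decomps)]
                 ).to_csv(out / "variance_decomposition.csv", index=False)
    return {"n_pairs": sizes["n_pairs"],
            "population_size": sizes["n_walks"] * sizes["walk_length"],
            "n_integrations": circuit.n_integrations}


def _stage_evolve(circuit, cfg, sizes, out):
    from .evolution import EvolutionConfig, evolve, evolution_summary
    from .sampling import sample_viable

    scfg = SamplingConfig(n_samples=1, seed=cfg.seed, target_class="normal")
    founders, _, _ = sample_viable(circuit, 1, scfg, max_attempts=10_000_000)
    ecfg = EvolutionConfig(N=sizes["evo_N"], generations=sizes["evo_generations"],
                           seed=cfg.seed + 1)
    trace = evolve(circuit, founders[0], ecfg)
    rows = []
    for gen in range(trace.S.shape[0]):
        for j, name in enumerate(PARAM_NAMES):
            rows.append({"generation": gen, "parameter": name,
                         "S": trace.S[gen, j], "abs_S": abs(trace.S[gen, j]),
                         "rank": trace.ranks[gen, j]})
    pd.DataFrame(rows).to_csv(out / "evolution.csv", index=False)
    df, curves, stats = evolution_summary(trace)
    payload = {
        "seed": cfg.seed, "stats": stats,
        "per_parameter": {
            name: {"tau_half": int(df.loc[name, "tau_half"]),
                   "censored": bool(df.loc[name, "censored"]),
                   "rho": [float(x) for x in curves[name]]}
            for name in PARAM_NAMES},
        "fallback_generations": trace.fallback_generations,
    }
    (out / "evolution_summary.json").write_text(json.dumps(payload, indent=2))
    return {"generations": sizes["evo_generations"], "N": sizes["evo_N"],
            "n_integrations": circuit.n_integrations}


def _stage_report(circuit, cfg, sizes, out):
    """Compile summary tables from artifacts already present in out_dir."""
    report = {}
    vol = out / "volumes.json"
    if vol.exists():
        report["volumes"] = json.loads(vol.read_text())
    imp = out / "importance.csv"
    if imp.exists():
        from .importance import rank_distribution

        df = pd.read_csv(imp)
        rank_mat = (df.pivot_table(index="set_id", columns="parameter",
                                   values="rank_S")
                    .reindex(columns=list(PARAM_NAMES)).to_numpy())
        hist, ranges = rank_distribution(rank_mat)
        report["sensitivity_rank_ranges"] = {
            p: [int(ranges.loc[p, "min_rank"]), int(ranges.loc[p, "max_rank"])]
            for p in PARAM_NAMES}
        logs = np.log10(np.maximum(df.groupby("parameter")["abs_S"].max(), 1e-300)
                        / np.maximum(df.groupby("parameter")["abs_S"].min(), 1e-300))
        report["abs_S_span_orders"] = {p: float(logs[p]) for p in PARAM_NAMES}
    reg = out / "regression.csv"
    if reg.exists():
        from .populations import summarize_pair_study

        df = pd.read_csv(reg)
        for model in df["model"].unique():
            summary, hist, ranges = summarize_pair_study(df, model=model)
            report[f"{model}_regression"] = {
                "mean_frac_nonsignificant":
                    float(summary["frac_nonsignificant"].mean()),
                "neglog10p_span": summary["neglog10p_span"].to_dict(),
            }
    evo = out / "evolution_summary.json"
    if evo.exists():
        report["evolution"] = json.loads(evo.read_text())["stats"]
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return {"sections": sorted(report)}
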