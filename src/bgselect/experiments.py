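"""Scenario runners: the paradigmatic simulations and parameter sweeps.

Each runner wraps the simulator with one published protocol — default
gating, conflict with/without the subthalamic brake, phasic reward or
punishment feedback, the reward/punishment training study, end-state
comparisons across tonic dopamine levels, and the gating-latency curve as
a function of stimulus strength and tonic dopamine — and writes plain CSV
and JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    ModelParams,
    SynapticWeights,
    default_params,
    default_weights,
    params_to_dict,
    weights_to_dict,
)
from .network import (
    DEFAULT_DURATION,
    DopamineSchedule,
    GatingResult,
    LesionSpec,
    Stimulus,
    Trace,
    detect_gating,
    simulate_trial,
)
from .plasticity import LearningParams, TrainingConfig, WeightHistory, run_training

__all__ = [
    "ExperimentSpec",
    "LatencyCurve",
    "STIMULI",
    "run_scenario",
    "run_da_sweep",
    "run_latency_curve",
    "run_training_experiment",
]

# The published protocol stimuli (four-channel network).
STIMULI = {
    "default": (0.3, 0.8, 0.3, 0.2),
    "conflict": (0.85, 0.9, 0.85, 0.1),
    "feedback": (0.4, 0.8, 0.6, 0.5),
    "training": (0.15, 0.15, 0.9, 0.7),
    "da_sweep": (0.3, 0.3, 0.85, 0.3),
}


@dataclass
class ExperimentSpec:
    """One fully resolved scenario: stimulus, schedule, lesions, output."""

    name: str
    stimulus: Stimulus
    schedule: DopamineSchedule = field(default_factory=DopamineSchedule)
    lesions: LesionSpec = field(default_factory=LesionSpec)
    duration: float = DEFAULT_DURATION
    training: TrainingConfig | None = None
    output_dir: Path | None = None

    def resolved_config(self, p: ModelParams, w: SynapticWeights) -> dict:
        doc = {
            "name": self.name,
            "stimulus": self.stimulus.s.tolist(),
            "schedule": dataclasses.asdict(self.schedule),
            "lesions": dataclasses.asdict(self.lesions),
            "duration_ms": self.duration,
            "params": params_to_dict(p),
            "weights": weights_to_dict(w),
        }
        if self.training is not None:
            doc["training"] = dataclasses.asdict(self.training)
        return doc


@dataclass
class LatencyCurve:
    """Gating outcome per (tonic dopamine, stimulus amplitude) grid point."""

    rows: pd.DataFrame  # columns: tonic_DA, a, gated, latency_ms

    def min_gated_amplitude(self, tonic_da: float) -> float | None:
        """Smallest amplitude gated at this dopamine level, or None."""
        sub = self.rows[(self.rows.tonic_DA == tonic_da) & self.rows.gated]
        return float(sub.a.min()) if len(sub) else None

    def latency(self, tonic_da: float, a: float) -> float | None:
        sub = self.rows[
            np.isclose(self.rows.tonic_DA, tonic_da) & np.isclose(self.rows.a, a)
        ]
        if not len(sub) or not bool(sub.gated.iloc[0]):
            return None
        return float(sub.latency_ms.iloc[0])


def _write_outputs(
    spec: ExperimentSpec,
    trace: Trace,
    gating: GatingResult,
    p: ModelParams,
    w: SynapticWeights,
) -> None:
    out = Path(spec.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    trace.to_frame().to_csv(out / f"{spec.name}_trace.csv", index=False)
    (out / f"{spec.name}_gating.json").write_text(
        json.dumps(gating.to_dict(), indent=2)
    )
    (out / f"{spec.name}_manifest.json").write_text(
        json.dumps(spec.resolved_config(p, w), indent=2)
    )


def run_scenario(
    spec: ExperimentSpec,
    p: ModelParams | None = None,
    w: SynapticWeights | None = None,
) -> tuple[Trace, GatingResult]:
    """Simulate one scenario; write trace CSV + gating JSON if requested.

    Deterministic: identical specs byte-reproduce their CSV outputs.
    """
    p = p or default_params()
    w = w if w is not None else default_weights(p.N)
    trace = simulate_trial(w, spec.stimulus, spec.schedule, p, spec.duration,
                           spec.lesions)
    gating = detect_gating(trace, p.action_threshold)
    if spec.output_dir is not None:
        _write_outputs(spec, trace, gating, p, w)
    return trace, gating


def run_da_sweep(
    stimulus: Stimulus | np.ndarray = STIMULI["da_sweep"],
    tonic_levels: tuple[float, ...] = (0.35, 0.45, 0.55),
    p: ModelParams | None = None,
    w: SynapticWeights | None = None,
    duration: float = DEFAULT_DURATION,
) -> pd.DataFrame:
    """End-of-trial winner-channel activities at each tonic dopamine level.

    Returns one row per level with the winner's cortical, Go, NoGo, GPe,
    GPi and thalamic activities plus the (global) ChI activity, the winner
    index and its gating latency.
    """
    if not len(tonic_levels):
        raise ValueError("tonic_levels must be nonempty")
    if any(lv <= 0 for lv in tonic_levels):
        raise ValueError("tonic dopamine levels must be > 0")
    p = p or default_params()
    w = w if w is not None else default_weights(p.N)
    rows = []
    for lv in tonic_levels:
        trace, gating = run_scenario(
            ExperimentSpec("da_sweep", Stimulus(np.asarray(stimulus, float)),
                           DopamineSchedule(tonic=lv), duration=duration),
            p, w,
        )
        fin = trace.final()
        win = gating.winner
        k = (win - 1) if win is not None else int(np.argmax(fin["C"]))
        rows.append({
            "tonic_DA": lv,
            "winner": win,
            "latency_ms": gating.latency_ms.get(win),
            "C": fin["C"][k], "Go": fin["Go"][k], "NoGo": fin["NoGo"][k],
            "GPe": fin["GPe"][k], "GPi": fin["GPi"][k], "T": fin["T"][k],
            "ChI": fin["ChI"],
        })
    return pd.DataFrame(rows)


def run_latency_curve(
    tonic_levels: tuple[float, ...] = (0.35, 0.4, 0.45, 0.55),
    a_min: float = 0.31,
    a_max: float = 1.0,
    a_step: float = 0.01,
    channel: int = 3,
    base_level: float = 0.3,
    p: ModelParams | None = None,
    w: SynapticWeights | None = None,
    duration: float = DEFAULT_DURATION,
) -> LatencyCurve:
    """Gating latency vs stimulus amplitude at several tonic dopamine levels.

    For each level and each amplitude ``a`` on the grid, presents a
    stimulus that is ``base_level`` everywhere except ``a`` in ``channel``
    and records whether a response was gated and its latency. A missing
    latency means no acceptable response was gated within the trial.
    """
    if not len(tonic_levels):
        raise ValueError("tonic_levels must be nonempty")
    if not (0 < a_min <= a_max <= 1):
        raise ValueError("amplitude grid must lie within (0, 1]")
    p = p or default_params()
    w = w if w is not None else default_weights(p.N)
    n = int(round((a_max - a_min) / a_step))
    a_grid = np.round(a_min + a_step * np.arange(n + 1), 10)
    rows = []
    for lv in tonic_levels:
        for a in a_grid:
            s = np.full(p.N, base_level)
            s[channel - 1] = a
            trace = simulate_trial(w, s, DopamineSchedule(tonic=lv), p, duration)
            g = detect_gating(trace, p.action_threshold)
            rows.append({
                "tonic_DA": lv,
                "a": float(a),
                "gated": g.winner is not None,
                "latency_ms": g.latency_ms.get(g.winner) if g.winner else None,
            })
    return LatencyCurve(rows=pd.DataFrame(rows))


def run_training_experiment(
    stimulus: Stimulus | np.ndarray = STIMULI["training"],
    cfg: TrainingConfig = TrainingConfig(),
    lp: LearningParams = LearningParams(),
    p: ModelParams | None = None,
    w0: SynapticWeights | None = None,
    output_dir: Path | None = None,
    eval_duration: float = DEFAULT_DURATION,
) -> dict:
    """The full training study: weight trajectories plus before/after trials.

    Runs the training protocol, then presents the noiseless stimulus to
    the pretraining and post-training networks and reports both gating
    outcomes alongside the weight history.
    """
    p = p or default_params()
    w0 = w0 if w0 is not None else default_weights(p.N)
    stim = stimulus if isinstance(stimulus, Stimulus) else Stimulus(np.asarray(stimulus, float))
    history = run_training(w0, stim, cfg, lp, p)
    w_final = history.final_weights(w0)
    sched = DopamineSchedule(tonic=cfg.tonic_da)
    _, gating_before = run_scenario(
        ExperimentSpec("before", stim, sched, duration=eval_duration), p, w0)
    _, gating_after = run_scenario(
        ExperimentSpec("after", stim, sched, duration=eval_duration), p, w_final)
    result = {
        "history": history,
        "final_weights": w_final,
        "gating_before": gating_before,
        "gating_after": gating_after,
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        history.to_frame().to_csv(out / "weight_history.csv", index=False)
        (out / "training_outcomes.json").write_text(
            json.dumps(history.outcomes, indent=2))
        (out / "gating_before_after.json").write_text(json.dumps({
            "before": gating_before.to_dict(),
            "after": gating_after.to_dict(),
            "seed": cfg.seed,
        }, indent=2))
    return result
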