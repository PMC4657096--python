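"""Thresholded two-term Hebbian plasticity and the training protocol.

Weight change for a synapse from presynaptic unit j to striatal unit i:

    dw_ij = sigma * [y_pre_j - theta_PRE]_+ * (y_post_i - theta_POST)

The rectified presynaptic term gates learning to synapses from active
sources (the cortical winner, salient stimulus elements); the signed
postsynaptic term decides potentiation vs depression. There is no explicit
dopamine factor: dopamine acts only through the network, by displacing
striatal activity away from ``theta_POST`` during a phasic reward peak or
punishment dip. Without a phasic event the winner's striatal activity sits
near ``theta_POST`` and the update is negligible. Trained weights are
clipped to [0, w_max].

Training runs epochs of: noisy stimulus -> tonic trial -> gating decision
-> phasic feedback trial (reward if the target channel was gated,
punishment if a wrong channel was gated, nothing if none) -> one Hebb
update of the four cortico-/sensory-striatal matrices from activities
sampled at the end of the phasic window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelParams, SynapticWeights
from .network import (
    DopamineSchedule,
    LesionSpec,
    Stimulus,
    detect_gating,
    simulate_trial,
)

__all__ = [
    "LearningParams",
    "TrainingConfig",
    "WeightHistory",
    "hebb_update",
    "noisy_stimulus",
    "run_training",
]


@dataclass(frozen=True)
class LearningParams:
    """Hebb-rule constants: rate, pre/post thresholds, weight ceiling."""

    sigma: float = 0.1
    theta_PRE: float = 0.5
    theta_POST: float = 0.5
    w_max: float = 1.2  # must exceed every pretraining weight (max is 1.08)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        for name in ("theta_PRE", "theta_POST"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not self.w_max > 0:
            raise ValueError("w_max must be > 0")


@dataclass(frozen=True)
class TrainingConfig:
    """Protocol of one training run.

    ``feedback_sample_time`` is when pre/post activities are read for the
    Hebb update: the end of the 100–150 ms phasic-dopamine window, where
    striatal activities are maximally displaced from threshold.
    ``update_without_feedback`` applies the rule even on epochs where
    nothing was gated (the update is then negligible by construction);
    default is to skip such epochs.
    """

    epochs: int = 100
    noise_sd: float = 0.25
    target_channel: int = 4
    seed: int = 0
    tonic_da: float = 0.45
    reward_level: float = 0.9
    punishment_level: float = 0.0
    event_onset: float = 100.0
    event_duration: float = 50.0
    feedback_sample_time: float = 150.0
    trial_duration: float = 300.0
    chi_clamped: bool = False
    update_without_feedback: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target_channel < 1:
            raise ValueError("target_channel is 1-based and must be >= 1")


@dataclass
class WeightHistory:
    """Per-epoch snapshots of the four trainable matrices plus outcomes.

    ``snapshots[m]`` has shape (epochs+1, N, N); index 0 is the
    pretraining state. ``outcomes`` has one record per epoch with the
    gated channel (or None) and the feedback delivered.
    """

    snapshots: dict[str, np.ndarray]
    outcomes: list[dict]
    seed: int

    @property
    def epochs(self) -> int:
        return next(iter(self.snapshots.values())).shape[0] - 1

    def final_weights(self, base: SynapticWeights) -> SynapticWeights:
        """A copy of ``base`` with the trained matrices at their last state."""
        w = base.copy()
        for name, snap in self.snapshots.items():
            setattr(w, name, snap[-1].copy())
        return w

    def to_frame(self) -> pd.DataFrame:
        """Long CSV form: epoch, matrix, i, j, value (i, j 1-based)."""
        rows = []
        for name, snap in self.snapshots.items():
            E1, N, _ = snap.shape
            e, i, j = np.meshgrid(np.arange(E1), np.arange(N), np.arange(N),
                                  indexing="ij")
            rows.append(pd.DataFrame({
                "epoch": e.ravel(), "matrix": name,
                "i": i.ravel() + 1, "j": j.ravel() + 1,
                "value": snap.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)


def hebb_update(
    W: np.ndarray,
    y_pre: np.ndarray,
    y_post: np.ndarray,
    lp: LearningParams = LearningParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """One application of the two-term rule; returns the updated matrix.

    Rows of ``W`` index postsynaptic units, columns presynaptic units.
    Only entries where ``mask`` is True change (default: all); updated
    entries are clipped to [0, w_max].
    """
    W = np.asarray(W, dtype=float)
    y_pre = np.asarray(y_pre, dtype=float).reshape(-1)
    y_post = np.asarray(y_post, dtype=float).reshape(-1)
    if W.shape != (y_post.size, y_pre.size):
        raise ValueError(
            f"shape mismatch: W {W.shape}, post {y_post.size}, pre {y_pre.size}"
        )
    mask = np.ones(W.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if mask.shape != W.shape:
        raise ValueError("mask shape must match W")
    delta = lp.sigma * np.outer(y_post - lp.theta_POST,
                                np.maximum(y_pre - lp.theta_PRE, 0.0))
    out = W.copy()
    out[mask] = np.clip(W[mask] + delta[mask], 0.0, lp.w_max)
    return out


def noisy_stimulus(
    s: Stimulus | np.ndarray, noise_sd: float, rng: np.random.Generator
) -> Stimulus:
    """Additive Gaussian noise on each stimulus element, clamped to [0, 1]."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    sv = s.s if isinstance(s, Stimulus) else np.asarray(s, dtype=float)
    noisy = sv + rng.normal(0.0, noise_sd, size=sv.shape) if noise_sd > 0 else sv.copy()
    return Stimulus(np.clip(noisy, 0.0, 1.0))


def run_training(
    w0: SynapticWeights,
    s: Stimulus | np.ndarray,
    cfg: TrainingConfig = TrainingConfig(),
    lp: LearningParams = LearningParams(),
    p: ModelParams | None = None,
) -> WeightHistory:
    """Train the four striatal input matrices over ``cfg.epochs`` epochs.

    Each epoch: draw a noisy stimulus, run a tonic trial to see what the
    network gates, then deliver phasic dopamine feedback (reward peak if
    the target channel was gated, punishment dip for any other gated
    channel) in a second trial with the same stimulus, and apply one Hebb
    update from activities at ``cfg.feedback_sample_time``. Cortex-to-
    striatum matrices train their diagonals only (channel segregation);
    stimulus-to-striatum matrices train in full.
    """
    p = p or ModelParams()
    stim = s if isinstance(s, Stimulus) else Stimulus(np.asarray(s, dtype=float))
    if cfg.target_channel > p.N:
        raise ValueError(f"target_channel {cfg.target_channel} > N={p.N}")
    rng = np.random.default_rng(cfg.seed)
    w = w0.copy()
    N = p.N
    diag_mask = np.eye(N, dtype=bool)
    full_mask = np.ones((N, N), dtype=bool)
    lesions = LesionSpec(chi_clamped=cfg.chi_clamped)

    snaps = {name: np.empty((cfg.epochs + 1, N, N)) for name in w.TRAINABLE}
    for name in w.TRAINABLE:
        snaps[name][0] = getattr(w, name)
    outcomes: list[dict] = []

    for epoch in range(cfg.epochs):
        s_ep = noisy_stimulus(stim, cfg.noise_sd, rng)
        try:
            trial = simulate_trial(
                w, s_ep, DopamineSchedule(tonic=cfg.tonic_da),
                p, cfg.trial_duration, lesions,
            )
            gating = detect_gating(trial, p.action_threshold)
            feedback = None
            if gating.winner is not None:
                feedback = ("reward" if gating.winner == cfg.target_channel
                            else "punishment")
            if feedback is not None or cfg.update_without_feedback:
                if feedback is None:
                    sched = DopamineSchedule(tonic=cfg.tonic_da)
                else:
                    level = (cfg.reward_level if feedback == "reward"
                             else cfg.punishment_level)
                    sched = DopamineSchedule(
                        tonic=cfg.tonic_da, event_kind=feedback,
                        event_onset=cfg.event_onset,
                        event_duration=cfg.event_duration,
                        event_level=level,
                    )
                fb_trial = simulate_trial(
                    w, s_ep, sched, p, cfg.trial_duration, lesions,
                )
                at = fb_trial.at(cfg.feedback_sample_time)
                y_C, y_G, y_N = at["C"], at["Go"], at["NoGo"]
                w.W_GC = hebb_update(w.W_GC, y_C, y_G, lp, diag_mask)
                w.W_NC = hebb_update(w.W_NC, y_C, y_N, lp, diag_mask)
                w.W_GS = hebb_update(w.W_GS, s_ep.s, y_G, lp, full_mask)
                w.W_NS = hebb_update(w.W_NS, s_ep.s, y_N, lp, full_mask)
        except Exception as exc:
            raise RuntimeError(f"training failed at epoch {epoch}") from exc

        for name in w.TRAINABLE:
            snaps[name][epoch + 1] = getattr(w, name)
        outcomes.append({
            "epoch": epoch,
            "stimulus": s_ep.s.tolist(),
            "gated": gating.winner,
            "feedback": feedback,
        })

    return WeightHistory(snapshots=snaps, outcomes=outcomes, seed=cfg.seed)
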