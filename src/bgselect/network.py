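"""The coupled cortico–basal-ganglia–thalamic circuit and trial simulation.

The network couples, per action channel: motor cortex (C), Go and NoGo
striatal units, GPe, GPi and thalamus (T), plus two global scalar units —
the subthalamic nucleus (STN), driven by a conflict-energy readout of the
cortex, and a cholinergic interneuron (ChI), driven only by its tonic input
and dopamine. Net inputs per population:

    x_L_i   = sum_{j != i} l_ij * y_C_j                  (lateral state)
    x_C_i   = (W_CS s)_i + u_L_i + w_CT_ii * y_T_i
    x_G_i   = (W_GS s)_i + w_GC_ii * y_C_i + alpha*DA*(y_G_i - theta_G) + w_GH*y_H
    x_N_i   = (W_NS s)_i + w_NC_ii * y_C_i + beta*DA + w_NH*y_H
    x_E_i   = w_EN_ii * y_N_i + w_ESTN * y_STN + I_E
    x_I_i   = w_IG_ii * y_G_i + w_IE_ii * y_E_i + w_ISTN * y_STN + I_I
    x_STN   = k_E * E + sum_j w_STNE_j * y_E_j,   E = sum_{i != j} y_C_i y_C_j
    x_T_i   = w_TI_ii * y_I_i + w_TC_ii * y_C_i
    x_H     = I_H + gamma * DA

All states relax toward their net input with time constant ``tau`` (the
lateral state with ``tau_L``) and are advanced together with explicit Euler
steps from the zero (silent) initial state. Note the cortex receives the
lateral-inhibition state ``u_L`` directly, without a sigmoid.

Dopamine is an external signal: a tonic level plus an optional rectangular
phasic event (a reward peak or a punishment dip). Lesions clamp activities
after each step: ``y_STN = 0`` removes the hyperdirect brake, and the ChI
clamp pins ``y_H`` at its tonic fixed point, suppressing its phasic
response to dopamine events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelParams, SynapticWeights
from .core import sigmoid

__all__ = [
    "Stimulus",
    "DopamineSchedule",
    "LesionSpec",
    "NetworkState",
    "Trace",
    "GatingResult",
    "IntegrationError",
    "dopamine_at",
    "conflict_energy",
    "net_inputs",
    "chi_tonic_activity",
    "simulate_trial",
    "detect_gating",
]

POPULATIONS = ("C", "Go", "NoGo", "GPe", "GPi", "T", "STN", "ChI")


class IntegrationError(RuntimeError):
    """The coupled system produced a non-finite state."""

    def __init__(self, population: str, t_ms: float):
        self.population = population
        self.t_ms = t_ms
        super().__init__(
            f"non-finite state in population {population!r} at t={t_ms:.3f} ms"
        )


@dataclass(frozen=True)
class Stimulus:
    """A length-N input vector with elements in [0, 1]."""

    s: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float).reshape(-1))
        if np.any(self.s < 0) or np.any(self.s > 1):
            raise ValueError(f"stimulus elements must lie in [0, 1], got {self.s}")

    def __len__(self) -> int:
        return self.s.size


@dataclass(frozen=True)
class DopamineSchedule:
    """Tonic dopamine plus an optional rectangular phasic event.

    ``reward`` raises dopamine to ``event_level`` (default 0.9, double the
    healthy tonic 0.45) during [onset, onset+duration); ``punishment``
    drops it (default to 0). Onset/duration default to the 100–150 ms
    window used for all phasic-feedback trials.
    """

    tonic: float = 0.45
    event_kind: str = "none"  # none | reward | punishment
    event_onset: float = 100.0
    event_duration: float = 50.0
    event_level: float | None = None

    def __post_init__(self) -> None:
        if self.tonic < 0:
            raise ValueError("tonic dopamine must be >= 0")
        if self.event_kind not in ("none", "reward", "punishment"):
            raise ValueError(f"unknown event kind {self.event_kind!r}")
        if self.event_duration < 0:
            raise ValueError("event_duration must be >= 0")
        if self.event_level is None:
            level = {"none": self.tonic, "reward": 0.9, "punishment": 0.0}[self.event_kind]
            object.__setattr__(self, "event_level", level)
        if self.event_level < 0:
            raise ValueError("event_level must be >= 0")

    @property
    def event_end(self) -> float:
        return self.event_onset + self.event_duration


@dataclass(frozen=True)
class LesionSpec:
    """Structural manipulations applied during a trial."""

    stn_off: bool = False      # clamp y_STN to 0 (no hyperdirect pathway)
    chi_clamped: bool = False  # pin y_H at its tonic fixed point (no phasic ChI)


@dataclass
class NetworkState:
    """Membrane states and activities of every population."""

    u_C: np.ndarray
    u_L: np.ndarray
    u_G: np.ndarray
    u_N: np.ndarray
    u_E: np.ndarray
    u_I: np.ndarray
    u_T: np.ndarray
    u_STN: float
    u_H: float
    y_C: np.ndarray = field(init=False)
    y_G: np.ndarray = field(init=False)
    y_N: np.ndarray = field(init=False)
    y_E: np.ndarray = field(init=False)
    y_I: np.ndarray = field(init=False)
    y_T: np.ndarray = field(init=False)
    y_STN: float = field(init=False)
    y_H: float = field(init=False)

    @classmethod
    def zeros(cls, N: int, p: ModelParams) -> "NetworkState":
        z = lambda: np.zeros(N)
        st = cls(u_C=z(), u_L=z(), u_G=z(), u_N=z(), u_E=z(), u_I=z(), u_T=z(),
                 u_STN=0.0, u_H=0.0)
        st.refresh_activities(p)
        return st

    def refresh_activities(self, p: ModelParams) -> None:
        sg = p.sigmoid
        self.y_C = sigmoid(self.u_C, sg)
        self.y_G = sigmoid(self.u_G, sg)
        self.y_N = sigmoid(self.u_N, sg)
        self.y_E = sigmoid(self.u_E, sg)
        self.y_I = sigmoid(self.u_I, sg)
        self.y_T = sigmoid(self.u_T, sg)
        self.y_STN = sigmoid(self.u_STN, sg)
        self.y_H = sigmoid(self.u_H, sg)


@dataclass
class Trace:
    """Time series of every population's activity over one trial."""

    times: np.ndarray                   # ms, shared grid
    activity: dict[str, np.ndarray]     # population -> (T, N) or (T,) series
    E_series: np.ndarray                # cortical conflict energy
    DA_series: np.ndarray               # dopamine level

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_ms, population, unit, activity.

        The conflict energy E and dopamine DA appear as pseudo-populations
        with unit 0.
        """
        rows = []
        for pop, series in self.activity.items():
            arr = np.atleast_2d(series.T).T  # (T,) -> (T, 1)
            for unit in range(arr.shape[1]):
                rows.append(pd.DataFrame({
                    "time_ms": self.times,
                    "population": pop,
                    "unit": unit + 1 if arr.shape[1] > 1 else 0,
                    "activity": arr[:, unit],
                }))
        rows.append(pd.DataFrame({
            "time_ms": self.times, "population": "E", "unit": 0,
            "activity": self.E_series,
        }))
        rows.append(pd.DataFrame({
            "time_ms": self.times, "population": "DA", "unit": 0,
            "activity": self.DA_series,
        }))
        return pd.concat(rows, ignore_index=True)

    def at(self, t_ms: float) -> dict[str, np.ndarray | float]:
        """Activities of every population at the grid point nearest ``t_ms``."""
        k = int(np.argmin(np.abs(self.times - t_ms)))
        out: dict[str, np.ndarray | float] = {}
        for pop, series in self.activity.items():
            out[pop] = series[k] if series.ndim > 1 else float(series[k])
        return out

    def final(self) -> dict[str, np.ndarray | float]:
        return self.at(self.times[-1])


@dataclass(frozen=True)
class GatingResult:
    """Which channels were gated, when, and which one won."""

    gated_channels: tuple[int, ...]        # 1-based channel indices
    latency_ms: dict[int, float]           # first threshold crossing per gated channel
    winner: int | None                     # earliest-crossing gated channel

    def to_dict(self) -> dict:
        return {
            "gated": list(self.gated_channels),
            "winner": self.winner,
            "latency_ms": {str(k): v for k, v in self.latency_ms.items()},
        }


def dopamine_at(schedule: DopamineSchedule, t: float) -> float:
    """Dopamine level at time ``t`` (ms): rectangular phasic pulse on tonic."""
    if schedule.event_kind != "none" and schedule.event_onset <= t < schedule.event_end:
        return schedule.event_level
    return schedule.tonic


def conflict_energy(y_C: np.ndarray) -> float:
    """Cortical conflict energy: sum over ordered pairs i != j of y_i * y_j.

    Zero when at most one unit is active; grows quadratically as several
    units become co-active, which is what drives the STN brake.
    """
    y = np.asarray(y_C, dtype=float)
    total = float(np.sum(y)) ** 2 - float(np.sum(y * y))
    return max(total, 0.0)


def chi_tonic_activity(p: ModelParams, tonic_da: float) -> float:
    """Fixed-point ChI activity under constant dopamine: sigma(I_H + gamma*DA)."""
    return float(sigmoid(p.I_H + p.gamma * tonic_da, p.sigmoid))


def net_inputs(
    state: NetworkState,
    s: Stimulus | np.ndarray,
    DA: float,
    w: SynapticWeights,
    p: ModelParams,
) -> dict[str, np.ndarray | float]:
    """Per-population net inputs for the current state (one time point)."""
    sv = s.s if isinstance(s, Stimulus) else np.asarray(s, dtype=float)
    if sv.size != p.N:
        raise ValueError(f"stimulus has {sv.size} elements, expected N={p.N}")
    E = conflict_energy(state.y_C)
    x = {
        "L": w.L @ state.y_C,
        "C": w.W_CS @ sv + state.u_L + np.diag(w.W_CT) * state.y_T,
        "Go": w.W_GS @ sv + np.diag(w.W_GC) * state.y_C
              + p.alpha * DA * (state.y_G - p.theta_G) + w.w_GH * state.y_H,
        "NoGo": w.W_NS @ sv + np.diag(w.W_NC) * state.y_C
                + p.beta * DA + w.w_NH * state.y_H,
        "GPe": np.diag(w.W_EN) * state.y_N + w.w_ESTN * state.y_STN + p.I_E,
        "GPi": np.diag(w.W_IG) * state.y_G + np.diag(w.W_IE) * state.y_E
               + w.w_ISTN * state.y_STN + p.I_I,
        "STN": w.k_E * E + float(w.W_STNE @ state.y_E),
        "T": np.diag(w.W_TI) * state.y_I + np.diag(w.W_TC) * state.y_C,
        "ChI": p.I_H + p.gamma * DA,
    }
    return x


DEFAULT_DURATION = 600.0  # ms; long enough for conflict trials to resolve


def simulate_trial(
    w: SynapticWeights,
    s: Stimulus | np.ndarray,
    schedule: DopamineSchedule = DopamineSchedule(),
    p: ModelParams | None = None,
    duration: float = DEFAULT_DURATION,
    lesions: LesionSpec = LesionSpec(),
    backend: str = "numba",
) -> Trace:
    """Advance the full circuit through one trial from the silent state.

    The stimulus is on for the whole trial; dopamine follows ``schedule``.
    Activities of every population, the conflict energy E and the dopamine
    level are recorded at every Euler step (including t=0).

    ``backend="numba"`` (default) runs the compiled loop; ``"numpy"`` runs
    the plain-numpy loop below, which is the readable reference the
    compiled kernel is tested against.

    Raises
    ------
    IntegrationError
        If any state becomes non-finite, naming the first offending
        population and the time.
    """
    p = p or ModelParams()
    if isinstance(s, Stimulus):
        stim = s
    else:
        stim = Stimulus(np.asarray(s, dtype=float))
    sv = stim.s
    if sv.size != p.N or w.N != p.N:
        raise ValueError(
            f"dimension mismatch: N={p.N}, stimulus {sv.size}, weights {w.N}"
        )
    if schedule.event_kind != "none" and duration < schedule.event_end:
        raise ValueError(
            f"duration {duration} ms ends before the scheduled dopamine event "
            f"({schedule.event_end} ms)"
        )

    dt = p.integrator.dt
    tau = p.integrator.tau
    tau_L = p.integrator.tau_L
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    N = p.N

    # flatten weights once; diagonal matrices reduce to vectors
    l_mat = w.L
    w_cs, w_ct = w.W_CS, np.diag(w.W_CT).copy()
    w_gs, w_gc = w.W_GS, np.diag(w.W_GC).copy()
    w_ns, w_nc = w.W_NS, np.diag(w.W_NC).copy()
    w_en, w_ie, w_ig = np.diag(w.W_EN).copy(), np.diag(w.W_IE).copy(), np.diag(w.W_IG).copy()
    w_tc, w_ti = np.diag(w.W_TC).copy(), np.diag(w.W_TI).copy()
    w_stne = w.W_STNE
    cs_s = w_cs @ sv
    gs_s = w_gs @ sv
    ns_s = w_ns @ sv
    sg = p.sigmoid
    chi_clamp_level = chi_tonic_activity(p, schedule.tonic)

    if backend == "numba":
        from ._kernel import POP_CODES, run_trial_kernel

        rec6, rec_STN, rec_H, E_series, DA_series, fail_pop, fail_t = run_trial_kernel(
            n_steps, dt, tau, tau_L, sg.a, sg.u0, N,
            l_mat, cs_s, gs_s, ns_s,
            w_ct, w_gc, w_nc, w_en, w_ie, w_ig, w_tc, w_ti, w_stne,
            float(w.w_ESTN), float(w.w_ISTN), float(w.k_E),
            float(w.w_GH), float(w.w_NH),
            p.alpha, p.beta, p.gamma, p.theta_G, p.I_E, p.I_I, p.I_H,
            schedule.tonic, schedule.event_kind != "none",
            schedule.event_onset, schedule.event_end, schedule.event_level,
            lesions.stn_off, lesions.chi_clamped, chi_clamp_level,
        )
        if fail_pop >= 0:
            raise IntegrationError(POP_CODES[fail_pop], fail_t)
        activity = {
            "C": rec6[0], "Go": rec6[1], "NoGo": rec6[2],
            "GPe": rec6[3], "GPi": rec6[4], "T": rec6[5],
            "STN": rec_STN, "ChI": rec_H,
        }
        return Trace(times=times, activity=activity,
                     E_series=E_series, DA_series=DA_series)
    if backend != "numpy":
        raise ValueError(f"unknown backend {backend!r}")

    u = {k: np.zeros(N) for k in ("C", "L", "Go", "NoGo", "GPe", "GPi", "T")}
    u_STN = 0.0
    u_H = 0.0

    rec = {k: np.empty((n_steps + 1, N)) for k in ("C", "Go", "NoGo", "GPe", "GPi", "T")}
    rec_STN = np.empty(n_steps + 1)
    rec_H = np.empty(n_steps + 1)
    E_series = np.empty(n_steps + 1)
    DA_series = np.empty(n_steps + 1)

    kd, ad = dt / tau, dt / tau_L
    y_C = sigmoid(u["C"], sg)
    y_G = sigmoid(u["Go"], sg)
    y_N = sigmoid(u["NoGo"], sg)
    y_E = sigmoid(u["GPe"], sg)
    y_I = sigmoid(u["GPi"], sg)
    y_T = sigmoid(u["T"], sg)
    y_STN = 0.0 if lesions.stn_off else float(sigmoid(u_STN, sg))
    y_H = chi_clamp_level if lesions.chi_clamped else float(sigmoid(u_H, sg))

    for k in range(n_steps + 1):
        t = times[k]
        DA = dopamine_at(schedule, t)
        E = float(np.sum(y_C)) ** 2 - float(np.sum(y_C * y_C))

        rec["C"][k] = y_C
        rec["Go"][k] = y_G
        rec["NoGo"][k] = y_N
        rec["GPe"][k] = y_E
        rec["GPi"][k] = y_I
        rec["T"][k] = y_T
        rec_STN[k] = y_STN
        rec_H[k] = y_H
        E_series[k] = E
        DA_series[k] = DA
        if k == n_steps:
            break

        x_L = l_mat @ y_C
        x_C = cs_s + u["L"] + w_ct * y_T
        x_G = gs_s + w_gc * y_C + p.alpha * DA * (y_G - p.theta_G) + w.w_GH * y_H
        x_N = ns_s + w_nc * y_C + p.beta * DA + w.w_NH * y_H
        x_E = w_en * y_N + w.w_ESTN * y_STN + p.I_E
        x_I = w_ig * y_G + w_ie * y_E + w.w_ISTN * y_STN + p.I_I
        x_STN = w.k_E * E + float(w_stne @ y_E)
        x_T = w_ti * y_I + w_tc * y_C
        x_H = p.I_H + p.gamma * DA

        u["L"] += ad * (x_L - u["L"])
        u["C"] += kd * (x_C - u["C"])
        u["Go"] += kd * (x_G - u["Go"])
        u["NoGo"] += kd * (x_N - u["NoGo"])
        u["GPe"] += kd * (x_E - u["GPe"])
        u["GPi"] += kd * (x_I - u["GPi"])
        u["T"] += kd * (x_T - u["T"])
        u_STN += kd * (x_STN - u_STN)
        u_H += kd * (x_H - u_H)

        for name, arr in (("C", u["C"]), ("L", u["L"]), ("Go", u["Go"]),
                          ("NoGo", u["NoGo"]), ("GPe", u["GPe"]),
                          ("GPi", u["GPi"]), ("T", u["T"])):
            if not np.all(np.isfinite(arr)):
                raise IntegrationError(name, times[k + 1])
        if not (np.isfinite(u_STN) and np.isfinite(u_H)):
            raise IntegrationError("STN" if not np.isfinite(u_STN) else "ChI",
                                   times[k + 1])

        y_C = sigmoid(u["C"], sg)
        y_G = sigmoid(u["Go"], sg)
        y_N = sigmoid(u["NoGo"], sg)
        y_E = sigmoid(u["GPe"], sg)
        y_I = sigmoid(u["GPi"], sg)
        y_T = sigmoid(u["T"], sg)
        y_STN = 0.0 if lesions.stn_off else float(sigmoid(u_STN, sg))
        y_H = chi_clamp_level if lesions.chi_clamped else float(sigmoid(u_H, sg))

    activity = {
        "C": rec["C"], "Go": rec["Go"], "NoGo": rec["NoGo"],
        "GPe": rec["GPe"], "GPi": rec["GPi"], "T": rec["T"],
        "STN": rec_STN, "ChI": rec_H,
    }
    return Trace(times=times, activity=activity, E_series=E_series, DA_series=DA_series)


def detect_gating(trace: Trace, action_threshold: float = 0.95) -> GatingResult:
    """Find gated channels, their latencies, and the winner.

    A channel is gated when its cortical activity at the final time point
    is at or above ``action_threshold``; its latency is the first crossing
    time. The winner is the earliest-crossing gated channel, ties broken
    by the lowest channel index. Channels are numbered from 1.
    """
    y_C = trace.activity["C"]
    if y_C.shape[0] == 0:
        raise ValueError("empty trace")
    gated = []
    latency: dict[int, float] = {}
    for i in range(y_C.shape[1]):
        above = y_C[:, i] >= action_threshold
        if above[-1]:
            ch = i + 1
            gated.append(ch)
            latency[ch] = float(trace.times[int(np.argmax(above))])
    winner = min(gated, key=lambda ch: (latency[ch], ch)) if gated else None
    return GatingResult(gated_channels=tuple(gated), latency_ms=latency, winner=winner)
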