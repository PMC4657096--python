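"""Model parameters, synaptic weights, and config-file round-tripping.

The default :class:`ModelParams` and :class:`SynapticWeights` reproduce the
published default operating point of the circuit: a four-channel network in
which, at rest, the output nucleus (GPi) is tonically active near saturation,
the GPe sits at roughly half activation, and cortex, striatum and thalamus
are silent. Connection signs follow the anatomy: striatal and pallidal
projections are inhibitory, cortical, thalamic and subthalamic projections
excitatory.

Configs are plain YAML/JSON documents with two blocks, ``params`` and
``weights``; :func:`load_config` / :func:`dump_config` round-trip them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import IntegratorConfig, SigmoidParams

__all__ = [
    "ModelParams",
    "SynapticWeights",
    "default_params",
    "default_weights",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class ModelParams:
    """Scalar constants of the network in its default state.

    Attributes
    ----------
    N : int
        Number of segregated action channels.
    theta_G : float
        Activity threshold of the dopamine contrast-enhancement effect on
        Go units: dopamine excites a Go unit above ``theta_G`` and
        inhibits it below.
    alpha, beta, gamma : float
        Dopamine gains on Go (``alpha > 0``), NoGo (``beta < 0``) and the
        cholinergic interneuron (``gamma < 0``).
    I_E, I_I, I_H : float
        Tonic external drives to GPe, GPi and the cholinergic unit; these
        set the tonic activity of the pallidum and ChI at rest.
    action_threshold : float
        Cortical activity above which a response counts as gated.
    """

    N: int = 4
    theta_G: float = 0.3
    alpha: float = 1.0
    beta: float = -1.0
    gamma: float = -1.0
    I_E: float = 1.0
    I_I: float = 3.0
    I_H: float = 1.25
    action_threshold: float = 0.95
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"need at least 2 action channels, got N={self.N}")
        if not self.alpha > 0:
            raise ValueError("alpha (Go dopamine gain) must be > 0")
        if not self.beta < 0:
            raise ValueError("beta (NoGo dopamine gain) must be < 0")
        if not self.gamma < 0:
            raise ValueError("gamma (ChI dopamine gain) must be < 0")
        if not 0 < self.action_threshold < 1:
            raise ValueError("action_threshold must lie in (0, 1)")


def _diag(N: int, value: float) -> np.ndarray:
    return np.diag(np.full(N, float(value)))


def _full(N: int, diag: float, off: float) -> np.ndarray:
    m = np.full((N, N), float(off))
    np.fill_diagonal(m, float(diag))
    return m


@dataclass
class SynapticWeights:
    """The 18 connection matrices/scalars of the network (pretraining).

    Matrices are stored with rows indexing the postsynaptic unit and
    columns the presynaptic unit. ``W_GC``, ``W_NC`` (cortex → striatum,
    diagonal) and ``W_GS``, ``W_NS`` (stimulus → striatum, full) are the
    four trainable sets; everything else is fixed.
    """

    L: np.ndarray          # cortical lateral inhibition, zero diagonal
    W_CS: np.ndarray       # stimulus -> cortex, full
    W_CT: np.ndarray       # thalamus -> cortex, diagonal
    W_GC: np.ndarray       # cortex -> Go, diagonal, trainable
    W_GS: np.ndarray       # stimulus -> Go, full, trainable
    W_NC: np.ndarray       # cortex -> NoGo, diagonal, trainable
    W_NS: np.ndarray       # stimulus -> NoGo, full, trainable
    W_EN: np.ndarray       # NoGo -> GPe, diagonal, inhibitory
    W_IE: np.ndarray       # GPe -> GPi, diagonal, inhibitory
    W_IG: np.ndarray       # Go -> GPi, diagonal, inhibitory
    W_TC: np.ndarray       # cortex -> thalamus, diagonal
    W_TI: np.ndarray       # GPi -> thalamus, diagonal, inhibitory
    w_ESTN: float          # STN -> GPe, scalar, excitatory
    w_ISTN: float          # STN -> GPi, scalar, excitatory (hyperdirect brake)
    k_E: float             # cortical conflict energy -> STN gain
    W_STNE: np.ndarray     # GPe -> STN, length-N row, inhibitory
    w_GH: float            # ChI -> Go, scalar, inhibitory
    w_NH: float            # ChI -> NoGo, scalar, excitatory

    _DIAGONAL = ("W_CT", "W_GC", "W_NC", "W_EN", "W_IE", "W_IG", "W_TC", "W_TI")
    _EXCITATORY = ("W_CS", "W_CT", "W_GC", "W_GS", "W_NC", "W_NS", "W_TC")
    _INHIBITORY = ("L", "W_EN", "W_IE", "W_IG", "W_TI", "W_STNE")
    TRAINABLE = ("W_GC", "W_NC", "W_GS", "W_NS")

    @property
    def N(self) -> int:
        return self.L.shape[0]

    def __post_init__(self) -> None:
        for name in (
            "L", "W_CS", "W_CT", "W_GC", "W_GS", "W_NC", "W_NS",
            "W_EN", "W_IE", "W_IG", "W_TC", "W_TI",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.W_STNE = np.asarray(self.W_STNE, dtype=float).reshape(-1)
        self.validate()

    def validate(self) -> None:
        N = self.N
        for name in (
            "L", "W_CS", "W_CT", "W_GC", "W_GS", "W_NC", "W_NS",
            "W_EN", "W_IE", "W_IG", "W_TC", "W_TI",
        ):
            m = getattr(self, name)
            if m.shape != (N, N):
                raise ValueError(f"{name} must be {N}x{N}, got {m.shape}")
        if self.W_STNE.shape != (N,):
            raise ValueError(f"W_STNE must have length {N}")
        if np.any(np.diag(self.L) != 0):
            raise ValueError("lateral-inhibition matrix L must have zero diagonal")
        for name in self._DIAGONAL:
            m = getattr(self, name)
            if np.any(m[~np.eye(N, dtype=bool)] != 0):
                raise ValueError(f"{name} must be diagonal")
        for name in self._EXCITATORY:
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} is excitatory; entries must be >= 0")
        for name in self._INHIBITORY:
            if np.any(getattr(self, name) > 0):
                raise ValueError(f"{name} is inhibitory; entries must be <= 0")
        for scalar, sign in (("w_ESTN", +1), ("w_ISTN", +1), ("k_E", +1),
                             ("w_NH", +1), ("w_GH", -1)):
            v = getattr(self, scalar)
            if sign * v < 0:
                kind = "excitatory" if sign > 0 else "inhibitory"
                raise ValueError(f"{scalar} is {kind}; got {v}")

    def copy(self) -> "SynapticWeights":
        kw = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            kw[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return SynapticWeights(**kw)


def default_params(**overrides) -> ModelParams:
    """The published default parameter set (four channels)."""
    return dataclasses.replace(ModelParams(), **overrides) if overrides else ModelParams()


def default_weights(N: int = 4) -> SynapticWeights:
    """The published pretraining synaptic values for an N-channel network."""
    return SynapticWeights(
        L=_full(N, 0.0, -1.2),
        W_CS=_full(N, 1.1, 0.2),
        W_CT=_diag(N, 4.0),
        W_GC=_diag(N, 0.48),
        W_GS=_full(N, 0.9, 0.0),
        W_NC=_diag(N, 1.08),
        W_NS=_full(N, 0.1, 0.0),
        W_EN=_diag(N, -2.2),
        W_IE=_diag(N, -3.0),
        W_IG=_diag(N, -12.0),
        W_TC=_diag(N, 3.0),
        W_TI=_diag(N, -3.0),
        w_ESTN=1.0,
        w_ISTN=14.0,
        k_E=7.0,
        W_STNE=np.full(N, -1.0),
        w_GH=-1.0,
        w_NH=1.0,
    )


# --- config serialization ---------------------------------------------------

_SCALAR_WEIGHTS = ("w_ESTN", "w_ISTN", "k_E", "w_GH", "w_NH")
_MATRIX_WEIGHTS = (
    "L", "W_CS", "W_CT", "W_GC", "W_GS", "W_NC", "W_NS",
    "W_EN", "W_IE", "W_IG", "W_TC", "W_TI",
)


def params_to_dict(p: ModelParams) -> dict:
    return {
        "N": p.N,
        "dt": p.integrator.dt,
        "tau": p.integrator.tau,
        "tau_L": p.integrator.tau_L,
        "a": p.sigmoid.a,
        "u0": p.sigmoid.u0,
        "theta_G": p.theta_G,
        "alpha": p.alpha,
        "beta": p.beta,
        "gamma": p.gamma,
        "I_E": p.I_E,
        "I_I": p.I_I,
        "I_H": p.I_H,
        "action_threshold": p.action_threshold,
    }


def params_from_dict(d: dict) -> ModelParams:
    d = dict(d)
    sig = SigmoidParams(a=d.pop("a", 4.0), u0=d.pop("u0", 1.0))
    integ = IntegratorConfig(
        dt=d.pop("dt", 0.1), tau=d.pop("tau", 10.0), tau_L=d.pop("tau_L", 50.0)
    )
    return ModelParams(sigmoid=sig, integrator=integ, **d)


def weights_to_dict(w: SynapticWeights) -> dict:
    out: dict = {}
    for name in _MATRIX_WEIGHTS:
        out[name] = getattr(w, name).tolist()
    out["W_STNE"] = w.W_STNE.tolist()
    for name in _SCALAR_WEIGHTS:
        out[name] = float(getattr(w, name))
    return out


def weights_from_dict(d: dict) -> SynapticWeights:
    return SynapticWeights(**{k: d[k] for k in (*_MATRIX_WEIGHTS, "W_STNE", *_SCALAR_WEIGHTS)})


def load_config(path: str | Path) -> tuple[ModelParams, SynapticWeights]:
    """Read a ``{params: ..., weights: ...}`` YAML or JSON document.

    Either block may be omitted, in which case the defaults are used.
    """
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    doc = doc or {}
    params = params_from_dict(doc["params"]) if "params" in doc else default_params()
    weights = weights_from_dict(doc["weights"]) if "weights" in doc else default_weights(params.N)
    if weights.N != params.N:
        raise ValueError(
            f"config mismatch: params.N={params.N} but weights are {weights.N}-channel"
        )
    return params, weights


def dump_config(params: ModelParams, weights: SynapticWeights, path: str | Path) -> None:
    """Write params + weights as a YAML (or JSON) config document."""
    doc = {"params": params_to_dict(params), "weights": weights_to_dict(weights)}
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(doc, indent=2))
    else:
        p.write_text(yaml.safe_dump(doc, sort_keys=False))
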