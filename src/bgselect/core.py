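"""Single-unit dynamics shared by every population in the network.

Each model neuron is a leaky integrator followed by a static sigmoidal
nonlinearity: the membrane state ``u`` relaxes toward the net input ``x``
with time constant ``tau`` (``tau du/dt = -u + x``), and the normalized
firing rate is ``y = 1 / (1 + exp(-a (u - u0)))``, bounded in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SigmoidParams",
    "IntegratorConfig",
    "sigmoid",
    "euler_step",
]

# Clamp on the sigmoid exponent argument; far outside the operating range
# of the model (|a(u-u0)| < ~40 in practice) but prevents overflow warnings
# if an integration diverges.
_EXP_CLAMP = 500.0


@dataclass(frozen=True)
class SigmoidParams:
    """Static activation nonlinearity: slope ``a`` and center ``u0``.

    With the default ``a=4, u0=1`` a silent unit (u=0) has activity
    ~0.018, and activity 0.5 is reached at u=1.
    """

    a: float = 4.0
    u0: float = 1.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"sigmoid slope a must be > 0, got {self.a}")


@dataclass(frozen=True)
class IntegratorConfig:
    """Explicit-Euler time stepping for the membrane equations.

    Parameters
    ----------
    dt : float
        Integration step in ms. Must satisfy ``dt <= tau / 10`` so the
        explicit scheme stays well inside its stability region.
    tau : float
        Membrane time constant in ms (all populations).
    tau_L : float
        Time constant of the cortical lateral-inhibition state in ms.
    """

    dt: float = 0.1
    tau: float = 10.0
    tau_L: float = 50.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.tau_L > 0:
            raise ValueError(f"tau_L must be > 0, got {self.tau_L}")
        if not 0 < self.dt <= self.tau / 10.0:
            raise ValueError(
                f"dt must satisfy 0 < dt <= tau/10 = {self.tau / 10.0}, got {self.dt}"
            )


def sigmoid(u, p: SigmoidParams = SigmoidParams()):
    """Normalized firing rate of a unit with membrane state ``u``.

    Strictly increasing, strictly inside (0, 1) for finite ``u``.
    Accepts scalars or arrays. Raises on non-finite input, which in this
    model always signals a numerical blow-up upstream.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite membrane state passed to sigmoid")
    z = np.clip(-p.a * (u - p.u0), -_EXP_CLAMP, _EXP_CLAMP)
    out = 1.0 / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def euler_step(u, x, tau: float, dt: float):
    """One explicit-Euler update of ``tau du/dt = -u + x``.

    Returns ``u + (dt/tau) * (x - u)``; the fixed point ``u == x`` is
    preserved exactly. Scalar or array ``u``/``x``.
    """
    if dt <= 0 or tau <= 0:
        raise ValueError(f"dt and tau must be positive, got dt={dt}, tau={tau}")
    return u + (dt / tau) * (np.asarray(x, dtype=float) - u)
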