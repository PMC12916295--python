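"""Core neuronal operations: magnesium switch, firing rate, state drift.

The NMDA channel is both ligand- and voltage-gated: depolarisation relieves a
magnesium block of the channel pore.  The blockade latent ``blk`` enters
through ``alpha = exp(blk)``, which scales the voltage sensitivity of the
sigmoidal switch — larger ``blk`` means the channel needs more depolarisation
to conduct (stronger blockade), which is the memantine-like regime; smaller
``blk`` opens channels at lower depolarisation (the disease-like regime).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .errors import InvalidParameterError, StructuralError
from .params import (
    MicrocircuitParameters, ModelConfig, N_NODES, compile_trial,
)

#: saturating numerator of the modified switch (Results form)
MG_NUMERATOR_MODIFIED = 1.50265
#: saturating numerator of the standard, unmodified switch (Methods form)
MG_NUMERATOR_STANDARD = 1.5


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} must be finite")
    return arr


def alpha_from_blockade(blk):
    """Positive scale factor ``exp(blk)`` applied to the switch's voltage term."""
    return np.exp(_check_finite("blk", blk))


def mg_switch(V, blk=0.0, numerator: float = MG_NUMERATOR_MODIFIED):
    """Voltage-dependent relief of the NMDA magnesium block, modified form.

    ``m(V) = numerator / (1 + 0.33 exp(-0.06 exp(blk) V))``; bounded in
    (0, numerator), strictly increasing in V.
    """
    V = _check_finite("V", V)
    alpha = alpha_from_blockade(blk)
    return numerator / (1.0 + 0.33 * np.exp(-0.06 * alpha * V))


def mg_switch_standard(V):
    """The unmodified magnesium-block removal function (numerator 1.5)."""
    V = _check_finite("V", V)
    return MG_NUMERATOR_STANDARD / (1.0 + 0.33 * np.exp(-0.06 * V))


def firing_rate(V, slope: float = 0.1, threshold: float = -40.0):
    """Presynaptic firing of a population: logistic sigmoid of voltage in (0, 1)."""
    if not np.isfinite(slope) or slope <= 0:
        raise InvalidParameterError("firing-rate slope must be finite and > 0")
    V = _check_finite("V", V)
    threshold = float(_check_finite("threshold", threshold))
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-slope * (V - threshold)))


@dataclass
class PopulationState:
    """Membrane potentials and channel conductances of all 8 populations."""

    V: np.ndarray
    g_ampa: np.ndarray
    g_gaba: np.ndarray
    g_nmda: np.ndarray
    g_leak: np.ndarray

    def __post_init__(self) -> None:
        for name in ("V", "g_ampa", "g_gaba", "g_nmda", "g_leak"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_NODES,):
                raise StructuralError(f"{name} must have shape ({N_NODES},)")
            if not np.all(np.isfinite(arr)):
                raise InvalidParameterError(f"{name} must be finite")
            setattr(self, name, arr)
        for name in ("g_ampa", "g_gaba", "g_nmda", "g_leak"):
            if np.any(getattr(self, name) < 0):
                raise InvalidParameterError(f"{name} must be non-negative")

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.V, self.g_ampa, self.g_gaba, self.g_nmda, self.g_leak])

    @classmethod
    def from_vector(cls, y: np.ndarray, clip: bool = False) -> "PopulationState":
        y = np.asarray(y, dtype=float)
        if y.shape != (5 * N_NODES,):
            raise StructuralError(f"state vector must have shape ({5 * N_NODES},)")
        parts = [y[i * N_NODES:(i + 1) * N_NODES].copy() for i in range(5)]
        if clip:
            parts[1:] = [np.maximum(p, 0.0) for p in parts[1:]]
        return cls(*parts)


def population_drift(state: PopulationState, params: MicrocircuitParameters,
                     u: float = 0.0, condition: int = 0) -> PopulationState:
    """Time derivative of the full network state under exogenous input ``u``.

    ``u`` is delivered to the configured input populations (spiny stellate by
    default) of both regions; ``condition`` selects whether the deviant
    self-connection modulation is active.  Derivative conductances may be
    negative (they are rates); they are returned without the non-negativity
    check applied to states.
    """
    pack = compile_trial(params.config, params.latents, condition)
    # evaluate at the bump peak with amplitude u so the delivered input is exactly u
    pack = pack[:-1] + (float(u),)
    dy = _engine.drift(state.to_vector(), pack[-3], *pack)
    out = PopulationState.__new__(PopulationState)
    out.V = dy[0:N_NODES]
    out.g_ampa = dy[N_NODES:2 * N_NODES]
    out.g_gaba = dy[2 * N_NODES:3 * N_NODES]
    out.g_nmda = dy[3 * N_NODES:4 * N_NODES]
    out.g_leak = dy[4 * N_NODES:5 * N_NODES]
    return out


def fixed_point(params: MicrocircuitParameters, condition: int = 0) -> PopulationState:
    """Numerical u=0 equilibrium of the drift (damped Picard iteration)."""
    pack = compile_trial(params.config, params.latents, condition)
    y, ok = _engine.fixed_point(*pack[:17])
    if not ok:
        raise InvalidParameterError(
            "fixed-point iteration failed to converge for this parameter set"
        )
    return PopulationState.from_vector(y, clip=True)


def drift_norm(params: MicrocircuitParameters, state: PopulationState,
               condition: int = 0) -> float:
    """Max-abs drift at ``state`` with no input — ~0 at an equilibrium."""
    d = population_drift(state, params, u=0.0, condition=condition)
    return float(np.max(np.abs(d.to_vector())))
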