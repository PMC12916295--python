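"""Model configuration and the latent parameterisation of the microcircuit.

The network is two cortical regions, each a four-population canonical
microcircuit (spiny stellate ``ss``, superficial pyramidal ``sp``, inhibitory
interneuron ``ii``, deep pyramidal ``dp``).  Each population carries a membrane
potential and AMPA/GABA/NMDA/leak conductances.  Subject-specific parameters
are *latent* (unconstrained, Gaussian priors); positivity of time constants and
gains is enforced by exponential transforms, e.g. ``tau = tau0 * exp(latent)``
and ``alpha_NMDA = exp(blk_NMDA)``.

Latent layout (one value per name, fixed order):

========================  =====================================================
``blk_l``, ``blk_r``      NMDA-blockade latent per region; ``exp(blk)`` scales
                          the voltage sensitivity of the magnesium switch
``ltau_ampa_*``           log-scaling of the AMPA conductance time constant
``ltau_gaba_*``           log-scaling of the GABA conductance time constant
``ltau_nmda_*``           log-scaling of the NMDA conductance time constant
``b_l``, ``b_r``          condition (deviant vs standard) log-modulation of the
                          self-inhibition gains of the region
``lgain``                 log-scaling of the observation gain, shared across
                          both regions (mirrors bilateral symmetry constraints)
========================  =====================================================
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .densities import GaussianDensity
from .errors import InvalidParameterError, StructuralError

POPULATIONS = ("ss", "sp", "ii", "dp")
REGIONS = ("l", "r")
N_POP = len(POPULATIONS)
N_NODES = N_POP * len(REGIONS)  # 8 populations across the network
N_STATES = 5 * N_NODES          # V + 4 conductances per population

LATENT_NAMES = (
    "blk_l", "blk_r",
    "ltau_ampa_l", "ltau_ampa_r",
    "ltau_gaba_l", "ltau_gaba_r",
    "ltau_nmda_l", "ltau_nmda_r",
    "b_l", "b_r",
    "lgain",
)

#: prior variances per latent; blockade and time constants use 1/64, the
#: condition modulation 1/16 and the observation gain a looser 1/8
PRIOR_VARIANCES = {
    "blk": 1.0 / 64, "ltau": 1.0 / 64, "b": 1.0 / 16, "lgain": 1.0 / 8,
}

# Intrinsic coupling (target population row <- source population column,
# order ss, sp, ii, dp).  Signs are fixed by the laminar wiring of the
# canonical microcircuit: ascending excitation ss->sp->dp, interneurons
# driven by all excitatory populations, GABAergic inhibition from ii plus
# self-inhibition on every population (the entries the condition effect
# modulates).  Magnitudes are package defaults chosen to give a stable fixed
# point and a damped evoked transient; they are configurable here.
_DEFAULT_EXC = (
    (0.0, 0.5, 0.0, 0.0),
    (2.0, 0.0, 0.0, 0.0),
    (1.0, 1.0, 0.0, 0.5),
    (0.0, 2.0, 0.0, 0.0),
)
_DEFAULT_INH = (
    (1.0, 0.0, 2.0, 0.0),
    (0.0, 1.0, 2.0, 0.0),
    (0.0, 0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0, 1.0),
)


@dataclass
class ModelConfig:
    """Fixed constants of the generative model (units: mV, ms)."""

    dt: float = 1.0
    t_end: float = 300.0
    # reversal potentials (mV); must satisfy v_gaba < v_leak < 0 < v_ampa <= v_nmda
    v_leak: float = -70.0
    v_ampa: float = 60.0
    v_gaba: float = -90.0
    v_nmda: float = 60.0
    capacitance: float = 8.0        # membrane capacitance (ms per unit conductance)
    g_leak: float = 1.0             # baseline leak conductance (unit conductance)
    tau_ampa: float = 4.0           # channel time constants (ms)
    tau_gaba: float = 16.0
    tau_nmda: float = 100.0
    tau_leak: float = 16.0
    firing_slope: float = 0.1       # logistic firing-rate slope (1/mV)
    firing_offset: float = 30.0     # threshold = v_leak + offset (mV)
    mg_numerator: float = 1.50265   # saturating value of the modified Mg switch
    nmda_ratio: float = 1.0         # NMDA drive relative to the AMPA drive
    # per-target-population multiplier of the NMDA drive (ss, sp, ii, dp);
    # the default enriches NMDA on inhibitory interneurons (NMDA-dependent
    # inhibition), keeping the blockade effect graded and stable
    nmda_weights: tuple = (0.25, 0.25, 2.0, 0.25)
    intrinsic_exc: tuple = _DEFAULT_EXC
    intrinsic_inh: tuple = _DEFAULT_INH
    forward_gain: float = 0.5       # sp (region l) -> ss & dp (region r)
    backward_gain: float = 0.25     # dp (region r) -> sp & ii (region l)
    input_populations: tuple = ("ss",)
    # effective input latency lumps subcortical/earlier cortical stages so the
    # deviance response peaks inside the canonical 140-160 ms window
    input_onset: float = 95.0       # thalamic bump peak latency (ms)
    input_width: float = 16.0       # bump width (ms)
    input_amplitude: float = 0.02   # bump peak (mV/ms on the voltage equation)
    input_to_conductances: bool = True  # deliver u to the dg/dt equations as printed
    n_modes: int = 8
    hanning: bool = True
    divergence_bound: float = 200.0  # |V| beyond this aborts integration

    def __post_init__(self) -> None:
        self.validate()

    # -- helpers --------------------------------------------------------
    def validate(self) -> None:
        if not (self.v_gaba < self.v_leak < 0.0 < self.v_ampa <= self.v_nmda):
            raise InvalidParameterError(
                "reversal potentials must satisfy v_gaba < v_leak < 0 < v_ampa <= v_nmda"
            )
        for name in ("capacitance", "g_leak", "tau_ampa", "tau_gaba", "tau_nmda",
                     "tau_leak", "firing_slope", "input_width", "dt"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if np.asarray(self.intrinsic_exc).shape != (N_POP, N_POP):
            raise StructuralError("intrinsic_exc must be 4x4")
        if np.asarray(self.intrinsic_inh).shape != (N_POP, N_POP):
            raise StructuralError("intrinsic_inh must be 4x4")

    def times(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt))
        return np.arange(n + 1) * self.dt

    @property
    def firing_threshold(self) -> float:
        return self.v_leak + self.firing_offset

    def to_dict(self) -> dict:
        d = asdict(self)
        d["intrinsic_exc"] = np.asarray(self.intrinsic_exc).tolist()
        d["intrinsic_inh"] = np.asarray(self.intrinsic_inh).tolist()
        d["input_populations"] = list(self.input_populations)
        d["nmda_weights"] = list(self.nmda_weights)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        for key in ("intrinsic_exc", "intrinsic_inh"):
            if key in d:
                d[key] = tuple(map(tuple, d[key]))
        for key in ("input_populations", "nmda_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_priors(free: tuple[str, ...] | None = None) -> GaussianDensity:
    """Zero-mean Gaussian priors over the latent layout.

    ``free`` restricts estimation: latents not listed get zero prior variance
    and stay clamped at their prior mean during inversion (the variance-mask
    convention for "all parameters fixed apart from the parameters of
    interest").
    """
    var = []
    for name in LATENT_NAMES:
        key = name.split("_")[0] if not name.startswith("ltau") else "ltau"
        v = PRIOR_VARIANCES[key]
        if free is not None and name not in free:
            v = 0.0
        var.append(v)
    return GaussianDensity(LATENT_NAMES, np.zeros(len(LATENT_NAMES)), np.array(var))


def latent_vector(latents: Mapping[str, float]) -> np.ndarray:
    """Order a latent dict into the canonical vector, zero-filling omissions."""
    unknown = set(latents) - set(LATENT_NAMES)
    if unknown:
        raise StructuralError(f"unknown latent names: {sorted(unknown)}")
    return np.array([float(latents.get(n, 0.0)) for n in LATENT_NAMES])


@dataclass
class MicrocircuitParameters:
    """All parameters of one subject's two-region model.

    ``latents`` holds the unconstrained values; :meth:`natural` reports the
    positive, natural-scale quantities obtained by exponential transform.
    """

    config: ModelConfig = field(default_factory=ModelConfig)
    latents: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vec = latent_vector(self.latents)  # validates names
        if not np.all(np.isfinite(vec)):
            raise InvalidParameterError("latent values must be finite")
        self.latents = {n: float(self.latents.get(n, 0.0)) for n in LATENT_NAMES}

    def natural(self) -> dict:
        c = self.config
        out = {"gain_scale": float(np.exp(self.latents["lgain"]))}
        for r in REGIONS:
            out[f"alpha_nmda_{r}"] = float(np.exp(self.latents[f"blk_{r}"]))
            out[f"tau_ampa_{r}"] = c.tau_ampa * float(np.exp(self.latents[f"ltau_ampa_{r}"]))
            out[f"tau_gaba_{r}"] = c.tau_gaba * float(np.exp(self.latents[f"ltau_gaba_{r}"]))
            out[f"tau_nmda_{r}"] = c.tau_nmda * float(np.exp(self.latents[f"ltau_nmda_{r}"]))
            out[f"b_scale_{r}"] = float(np.exp(self.latents[f"b_{r}"]))
        return out

    # -- serialisation (documented JSON schema) -------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config.to_dict(), "latents": self.latents,
                 "natural": self.natural()},
                fh, indent=2, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "MicrocircuitParameters":
        with open(path) as fh:
            d = json.load(fh)
        return cls(ModelConfig.from_dict(d["config"]), dict(d["latents"]))


def _region_slice(r: int) -> slice:
    return slice(r * N_POP, (r + 1) * N_POP)


def compile_trial(config: ModelConfig, latents: Mapping[str, float], condition: int):
    """Pack one condition's natural-scale arrays for the integration engine.

    ``condition`` is the between-trial regressor: 1 for the deviant evoked
    response, 0 for the standard (repetition 5).  Returns the positional tuple
    consumed by :mod:`nmda_dcm._engine`.
    """
    if condition not in (0, 1):
        raise InvalidParameterError("condition must be 0 (standard) or 1 (deviant)")
    lat = {n: float(latents.get(n, 0.0)) for n in LATENT_NAMES}
    c = config

    exc = np.asarray(c.intrinsic_exc, dtype=float)
    inh = np.asarray(c.intrinsic_inh, dtype=float)
    nw = np.asarray(c.nmda_weights, dtype=float)
    if nw.shape != (N_POP,):
        raise StructuralError("nmda_weights must have one entry per population")
    EA = np.zeros((N_NODES, N_NODES))
    EN = np.zeros((N_NODES, N_NODES))
    GI = np.zeros((N_NODES, N_NODES))
    for r in range(2):
        s = _region_slice(r)
        EA[s, s] = exc
        EN[s, s] = exc * c.nmda_ratio * nw[:, None]
        gi = inh.copy()
        # condition effect: log-scaling of the self-connections of the region
        gi[np.diag_indices(N_POP)] *= np.exp(lat[f"b_{REGIONS[r]}"] * condition)
        GI[s, s] = gi
    isp, iii, iss, idp = (POPULATIONS.index(p) for p in ("sp", "ii", "ss", "dp"))
    # extrinsic: forward l.sp -> r.ss & r.dp, backward r.dp -> l.sp & l.ii
    EA[N_POP + iss, isp] = EA[N_POP + idp, isp] = c.forward_gain
    EA[isp, N_POP + idp] = EA[iii, N_POP + idp] = c.backward_gain
    EN[N_POP + iss, isp] = c.forward_gain * c.nmda_ratio * nw[iss]
    EN[N_POP + idp, isp] = c.forward_gain * c.nmda_ratio * nw[idp]
    EN[isp, N_POP + idp] = c.backward_gain * c.nmda_ratio * nw[isp]
    EN[iii, N_POP + idp] = c.backward_gain * c.nmda_ratio * nw[iii]

    alpha = np.empty(N_NODES)
    tA = np.empty(N_NODES)
    tG = np.empty(N_NODES)
    tN = np.empty(N_NODES)
    for r, reg in enumerate(REGIONS):
        s = _region_slice(r)
        alpha[s] = np.exp(lat[f"blk_{reg}"])
        tA[s] = c.tau_ampa * np.exp(lat[f"ltau_ampa_{reg}"])
        tG[s] = c.tau_gaba * np.exp(lat[f"ltau_gaba_{reg}"])
        tN[s] = c.tau_nmda * np.exp(lat[f"ltau_nmda_{reg}"])

    umask = np.zeros(N_NODES)
    for p in c.input_populations:
        if p not in POPULATIONS:
            raise StructuralError(f"unknown input population {p!r}")
        for r in range(2):
            umask[r * N_POP + POPULATIONS.index(p)] = 1.0

    return (
        EA, EN, GI, alpha, tA, tG, tN,
        float(c.tau_leak), float(c.capacitance), float(c.g_leak),
        float(c.v_leak), float(c.v_ampa), float(c.v_gaba), float(c.v_nmda),
        float(c.mg_numerator), float(c.firing_slope), float(c.firing_threshold),
        umask, 1.0 if c.input_to_conductances else 0.0,
        float(c.input_onset), float(c.input_width), float(c.input_amplitude),
    )
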