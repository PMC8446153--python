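"""Model parameters and their validation.

The model couples four neuronal subpopulations (pyramidal cells, a second
pyramidal pool, dendrite-projecting SOM+ interneurons and soma-projecting
PV+ interneurons) through average post-synaptic potentials.  Each synapse
class has a gain (``A`` excitatory, ``B`` slow GABAergic, ``G`` fast
GABAergic, all in mV) and a time constant (``tau_a`` < ``tau_b`` for the
excitatory/slow-inhibitory kinetics, ``tau_g`` for the fast somatic
inhibition).  The dimensionless connectivity constants ``C1..C7`` scale the
average number of synaptic contacts between the subpopulations, and ``p``
is the mean rate of the external (thalamic/cortical) drive.

The ratio ``delta = tau_g/tau_a`` separates the fast somatic inhibition
from the slow dendritic kinetics and ``epsilon = tau_a/tau_b`` separates
those from the super-slow SOM+ loop, giving the model its three-time-scale
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
import math


@dataclass(frozen=True)
class SigmoidParams:
    """Wave-to-pulse sigmoid S(v) = vmax / (1 + exp(steepness*(v_half - v)))."""

    vmax: float = 5.0        # maximal population firing rate (s^-1)
    steepness: float = 0.56  # slope at half-activation (mV^-1)
    v_half: float = 6.0      # half-activation potential (mV)

    def __post_init__(self) -> None:
        if not (self.vmax > 0 and self.steepness > 0):
            raise ValueError("sigmoid vmax and steepness must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the four-population mass model.

    Defaults are the bursting-discharge reference set ('table1' preset).
    """

    A: float = 5.0        # excitatory synaptic gain (mV)
    B: float = 5.0        # slow (dendritic, SOM+) inhibitory gain (mV)
    G: float = 35.0       # fast (somatic, PV+) inhibitory gain (mV)
    p_mean: float = 90.0  # mean external input rate (s^-1)
    sigma: float = 0.0    # input-rate noise s.d. (s^-1); 0 = deterministic
    C1: float = 135.0
    C2: float = 108.0
    C3: float = 80.0      # pyramidal -> SOM+ contacts, main bifurcation knob
    C4: float = 25.0
    C5: float = 450.0     # pyramidal -> PV+ contacts, sets burst spike count
    C6: float = 121.0     # SOM+ -> PV+ contacts
    C7: float = 121.0     # PV+ -> pyramidal contacts
    tau_a: float = 0.01   # excitatory time constant (s)
    tau_b: float = 0.05   # slow inhibitory time constant (s)
    tau_g: float = 0.003  # fast inhibitory time constant (s)
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        for name in ("tau_a", "tau_b", "tau_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.tau_g < self.tau_a < self.tau_b):
            raise ValueError(
                "three-time-scale ordering tau_g < tau_a < tau_b violated"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def delta(self) -> float:
        """Fast/slow scale ratio tau_g / tau_a."""
        return self.tau_g / self.tau_a

    @property
    def epsilon(self) -> float:
        """Slow/super-slow scale ratio tau_a / tau_b."""
        return self.tau_a / self.tau_b

    def with_(self, **overrides) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    def geometry_key(self) -> tuple:
        """Hashable key of every parameter the super-slow manifold depends on.

        The implicit manifold equation contains neither B nor C3, so traces
        can be shared across scans over those two gains.
        """
        return (
            self.A, self.G, self.p_mean, self.C1, self.C2, self.C4,
            self.C5, self.C6, self.C7, self.tau_a, self.tau_b, self.tau_g,
            self.sigmoid.vmax, self.sigmoid.steepness, self.sigmoid.v_half,
        )


def table1() -> ModelParams:
    """The bursting-type reference parameter set (delta=0.3, epsilon=0.2)."""
    return ModelParams()


_SIGMOID_KEYS = {"vmax", "steepness", "v_half"}
_PARAM_KEYS = {f.name for f in fields(ModelParams)} - {"sigmoid"}


def params_from_dict(d: dict) -> ModelParams:
    """Build a parameter set from a flat mapping; unknown keys raise."""
    kw: dict = {}
    sg: dict = {}
    for k, v in d.items():
        if k in _PARAM_KEYS:
            kw[k] = float(v)
        elif k in _SIGMOID_KEYS:
            sg[k] = float(v)
        else:
            raise KeyError(f"unknown parameter key: {k!r}")
    if sg:
        kw["sigmoid"] = SigmoidParams(**{**SigmoidParams().__dict__, **sg})
    return ModelParams(**kw)


def params_to_dict(p: ModelParams) -> dict:
    """Flat key-value form, suitable for TOML serialization."""
    d = {f.name: getattr(p, f.name) for f in fields(p) if f.name != "sigmoid"}
    d.update(vmax=p.sigmoid.vmax, steepness=p.sigmoid.steepness,
             v_half=p.sigmoid.v_half)
    return d


def validate_anchors(p: ModelParams, rtol: float = 5e-3) -> None:
    """Reject a parameter parse that fails the reference derived quantities.

    The bursting reference set pins delta = 0.3, epsilon = 0.2, the fold
    points of the super-slow manifold at v0 = 1.2343 / 9.9976 and the
    degenerate transcritical gains at B = 16.7817 / 5.4817.  A parameter
    file claiming to be the reference set must reproduce them.
    """
    from . import manifold

    if not math.isclose(p.delta, 0.3, rel_tol=1e-9):
        raise ValueError(f"delta anchor failed: {p.delta} != 0.3")
    if not math.isclose(p.epsilon, 0.2, rel_tol=1e-9):
        raise ValueError(f"epsilon anchor failed: {p.epsilon} != 0.2")
    f1, f2 = manifold.fold_points(p)
    for got, want, name in (
        (f1.v0, 1.2343, "fold p1"),
        (f2.v0, 9.9976, "fold p2"),
        (manifold.transcritical_B(p, "p1"), 16.7817, "B_BP1"),
        (manifold.transcritical_B(p, "p2"), 5.4817, "B_BP2"),
    ):
        if not math.isclose(got, want, rel_tol=rtol):
            raise ValueError(f"anchor {name} failed: {got:.6f} vs {want}")
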