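"""Single-neuron biophysics.

Hodgkin-Huxley style single-compartment neurons with a fast sodium
current (I_Na), a delayed-rectifier potassium current (I_K), a leak
current (I_L) and, in conditionally bursting neurons, a persistent
(slowly inactivating) sodium current (I_NaP).  The slow inactivation of
I_NaP (time constant up to seconds, ``t_hmax``) is what allows a neuron
to burst intrinsically within a window of excitability set by its leak
reversal potential ``e_leak``: below the window the neuron is silent,
above it it spikes tonically.

Units are mV, ms, nS, pF and pA throughout, so that the membrane
equation closes dimensionally (pA / pF = mV / ms).

The functions here are the scalar/vector reference implementation of
the model equations; the time-stepping production path lives in
:mod:`spinalcpg.engine` and is cross-checked against these functions in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

__all__ = [
    "GATES",
    "ChannelKinetics",
    "KINETICS",
    "NeuronParams",
    "NeuronState",
    "steady_state",
    "time_constant",
    "ionic_currents",
    "synaptic_gate_derivative",
    "state_derivative",
    "SYN_ALPHA",
    "SYN_TAU",
    "SYN_V_HALF",
    "SYN_K",
    "syn_gate_steady_state",
]


@dataclass(frozen=True)
class ChannelKinetics:
    """Boltzmann steady state and cosh-reciprocal time constant of one gate.

    ``steady(V) = 1 / (1 + exp(sign * (V - v_half) / k))`` with
    ``sign = -1`` for activation gates and ``+1`` for inactivation
    gates, and ``tau(V) = tau_max / cosh((V - v_half) / k_tau)``.
    Instantaneous gates (``tau_max is None``) are evaluated
    algebraically at every step instead of being integrated.
    """

    name: str
    v_half: float  # mV
    k: float  # mV, slope of the Boltzmann
    activation: bool  # True: increases with V; False: inactivation
    tau_max: float | None = None  # ms; None -> instantaneous gate
    k_tau: float | None = None  # mV, width of the cosh profile

    @property
    def instantaneous(self) -> bool:
        return self.tau_max is None

    def steady(self, v):
        sign = -1.0 if self.activation else 1.0
        return 1.0 / (1.0 + np.exp(sign * (np.asarray(v, float) - self.v_half) / self.k))

    def tau(self, v, tau_max: float | None = None):
        if self.instantaneous and tau_max is None:
            raise ValueError(f"gate {self.name!r} is instantaneous; no time constant")
        t_max = self.tau_max if tau_max is None else tau_max
        return t_max / np.cosh((np.asarray(v, float) - self.v_half) / self.k_tau)


#: Channel kinetics of the five gates.  h_K is identically 1 and is not a
#: gate.  t_hmax (the peak h_NaP inactivation time constant) is a neuron
#: parameter, so the h_NaP entry stores ``tau_max=None`` semantics via
#: ``time_constant(..., t_hmax=...)``.
KINETICS: dict[str, ChannelKinetics] = {
    "m_na": ChannelKinetics("m_na", -42.5, 6.5, activation=True),
    "h_na": ChannelKinetics("h_na", -65.5, 10.2, activation=False, tau_max=35.2, k_tau=12.8),
    "m_nap": ChannelKinetics("m_nap", -52.0, 3.2, activation=True),
    "h_nap": ChannelKinetics("h_nap", -57.0, 5.0, activation=False, tau_max=np.nan, k_tau=8.0),
    "m_k": ChannelKinetics("m_k", -34.5, 5.0, activation=True, tau_max=10.0, k_tau=10.0),
}

GATES = tuple(KINETICS)

# First-order kinetics of the synaptic output gate s (AMPA-like):
# tau_s ds/dt = alpha_s s_inf(V) (1 - s) - s.  alpha_s is dimensionless
# and tau_s carries the time scale of both rise and decay; this reading
# of the gate equation reproduces the published two-cell voltage shifts
# and regime transitions under chemical coupling, whereas an alpha_s
# with units 1/ms (rise 15x faster) drives targets into sustained
# spiking or depolarization block at the tabulated weights.
SYN_ALPHA = 1.0  # dimensionless
SYN_TAU = 15.0  # ms
SYN_V_HALF = -20.0  # mV
SYN_K = 2.0  # mV


@dataclass
class NeuronParams:
    """Biophysical constants of one neuron.

    Conductances in nS, potentials in mV, capacitance in pF and
    ``t_hmax`` (peak I_NaP inactivation time constant) in ms.  When
    ``has_nap`` is false the persistent sodium current is absent and
    ``gbar_nap`` is treated as exactly zero.
    """

    c: float = 40.0
    gbar_na: float = 80.0
    gbar_k: float = 100.0
    g_leak: float = 1.0
    gbar_nap: float = 0.0
    e_na: float = 55.0
    e_k: float = -80.0
    e_leak: float = -70.0
    has_nap: bool = False
    t_hmax: float = 9000.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("membrane capacitance must be positive")
        for name in ("gbar_na", "gbar_k", "g_leak", "gbar_nap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.t_hmax <= 0:
            raise ValueError("t_hmax must be positive")

    @property
    def g_nap_eff(self) -> float:
        """Persistent sodium conductance actually entering the equations."""
        return self.gbar_nap if self.has_nap else 0.0

    def with_e_leak(self, e_leak: float) -> "NeuronParams":
        return replace(self, e_leak=e_leak)


def nap_burster(e_leak: float, gbar_nap: float = 4.0, t_hmax: float = 9000.0) -> NeuronParams:
    """Conditionally bursting neuron carrying I_NaP (default 4 nS)."""
    return NeuronParams(e_leak=e_leak, gbar_nap=gbar_nap, has_nap=True, t_hmax=t_hmax)


def simple_neuron(e_leak: float) -> NeuronParams:
    """Tonic-capable neuron without I_NaP."""
    return NeuronParams(e_leak=e_leak, has_nap=False)


@dataclass
class NeuronState:
    """Dynamical variables of one neuron.

    ``m_na`` and ``m_nap`` are not state: activation of both sodium
    channels is instantaneous and is evaluated as the steady state of
    the current V.  ``s`` is the synaptic output gate driving this
    neuron's outgoing chemical synapses.
    """

    v: float
    h_na: float
    h_nap: float
    m_k: float
    s: float = 0.0

    @classmethod
    def at_rest(cls, v: float, s: float = 0.0) -> "NeuronState":
        """State with every integrated gate at its steady value for V = v."""
        return cls(
            v=v,
            h_na=float(steady_state("h_na", v)),
            h_nap=float(steady_state("h_nap", v)),
            m_k=float(steady_state("m_k", v)),
            s=s,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.h_na, self.h_nap, self.m_k, self.s])


def steady_state(gate_id: str, v):
    """Voltage-dependent steady state of a gate, in [0, 1]."""
    try:
        kin = KINETICS[gate_id]
    except KeyError:
        raise KeyError(f"unknown gate {gate_id!r}; expected one of {GATES}") from None
    return kin.steady(v)


def time_constant(gate_id: str, v, t_hmax: float | None = None):
    """Voltage-dependent time constant (ms) of a non-instantaneous gate.

    For ``h_nap`` the peak value is the neuron parameter ``t_hmax`` and
    must be supplied.
    """
    try:
        kin = KINETICS[gate_id]
    except KeyError:
        raise KeyError(f"unknown gate {gate_id!r}; expected one of {GATES}") from None
    if kin.instantaneous:
        raise ValueError(f"gate {gate_id!r} is instantaneous; no time constant")
    if gate_id == "h_nap":
        if t_hmax is None:
            raise ValueError("h_nap time constant requires t_hmax")
        return kin.tau(v, tau_max=t_hmax)
    return kin.tau(v)


def ionic_currents(state: NeuronState, params: NeuronParams) -> tuple[float, float, float, float]:
    """(I_Na, I_NaP, I_K, I_L) in pA for the given state."""
    v = state.v
    m_na = float(steady_state("m_na", v))
    m_nap = float(steady_state("m_nap", v))
    i_na = params.gbar_na * m_na**3 * state.h_na * (v - params.e_na)
    i_nap = params.g_nap_eff * m_nap * state.h_nap * (v - params.e_na)
    i_k = params.gbar_k * state.m_k**4 * (v - params.e_k)
    i_leak = params.g_leak * (v - params.e_leak)
    return i_na, i_nap, i_k, i_leak


def syn_gate_steady_state(v):
    """Presynaptic drive s_inf(V) of the synaptic gate."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - SYN_V_HALF) / SYN_K))


def synaptic_gate_derivative(s, v):
    """ds/dt (1/ms) of the first-order synaptic output gate.

    Under sustained presynaptic depolarization (s_inf = 1) the gate
    relaxes to s* = alpha_s / (1 + alpha_s) = 1/2; under hyperpolarization
    it decays to 0 with time constant tau_s = 15 ms.
    """
    s = np.asarray(s, float)
    return (SYN_ALPHA * syn_gate_steady_state(v) * (1.0 - s) - s) / SYN_TAU


def state_derivative(
    state: NeuronState,
    params: NeuronParams,
    i_gap: float = 0.0,
    i_syn: float = 0.0,
) -> NeuronState:
    """Time derivative of the full per-neuron state.

    ``i_gap`` is the gap-junction sum ``sum_i g_ij (V_i - V_j)`` (pA),
    which enters the membrane equation as a depolarizing drive toward
    the neighbours' potentials; ``i_syn`` is the chemical synaptic
    current ``g_syn (sum_i w_ij s_i)(V_j - E_syn)`` (pA), which enters
    with a minus sign (depolarizing for V below E_syn = 0).
    """
    v = state.v
    i_na, i_nap, i_k, i_leak = ionic_currents(state, params)
    dv = (-(i_na + i_nap + i_k + i_leak + i_syn) + i_gap) / params.c
    dh_na = (float(steady_state("h_na", v)) - state.h_na) / float(time_constant("h_na", v))
    dh_nap = (float(steady_state("h_nap", v)) - state.h_nap) / float(
        time_constant("h_nap", v, t_hmax=params.t_hmax)
    )
    dm_k = (float(steady_state("m_k", v)) - state.m_k) / float(time_constant("m_k", v))
    ds = float(synaptic_gate_derivative(state.s, v))
    return NeuronState(v=dv, h_na=dh_na, h_nap=dh_nap, m_k=dm_k, s=ds)


def params_arrays(params: Iterable[NeuronParams]) -> dict[str, np.ndarray]:
    """Column arrays of per-neuron parameters for the vectorized engine."""
    plist = list(params)
    return {
        "c": np.array([p.c for p in plist]),
        "gbar_na": np.array([p.gbar_na for p in plist]),
        "gbar_k": np.array([p.gbar_k for p in plist]),
        "g_leak": np.array([p.g_leak for p in plist]),
        "g_nap": np.array([p.g_nap_eff for p in plist]),
        "e_na": np.array([p.e_na for p in plist]),
        "e_k": np.array([p.e_k for p in plist]),
        "e_leak": np.array([p.e_leak for p in plist]),
        "t_hmax": np.array([p.t_hmax for p in plist]),
    }
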