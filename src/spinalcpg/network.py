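"""Coupling structures and population randomization.

Neurons are coupled by bidirectional electrical synapses (gap
junctions, symmetric conductance matrix) and/or unidirectional
excitatory chemical synapses (directed weight matrix, AMPA-like with
reversal at 0 mV).  Heterogeneous populations draw leak reversal, leak
conductance and persistent sodium conductance per neuron from normal
distributions, mirroring the sparse, locally gap-coupled organisation
reported for spinal Shox2 interneurons (connection probabilities
p_gap ~ 0.3, p_syn ~ 0.1).

Aggregate coupling measures characterise total network input per
neuron: G = N * p_gap * g_gap (nS, electrical) and
W = N * p_syn * w_syn (dimensionless, chemical).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .neuron import NeuronParams, NeuronState

__all__ = [
    "G_SYN",
    "E_SYN",
    "check_gap_matrix",
    "gap_currents",
    "synaptic_currents",
    "sample_gap_connectivity",
    "sample_chemical_connectivity",
    "aggregate_coupling",
    "per_edge_strength",
    "PopulationSpec",
    "Population",
    "sample_population",
    "truncated_normal",
]

G_SYN = 1.0  # nS, unitary chemical synaptic conductance scaled by w_syn
E_SYN = 0.0  # mV, AMPA-like reversal


def check_gap_matrix(gap: np.ndarray) -> np.ndarray:
    """Validate a gap-junction conductance matrix (symmetric, zero diagonal, >= 0)."""
    gap = np.asarray(gap, float)
    if gap.ndim != 2 or gap.shape[0] != gap.shape[1]:
        raise ValueError("gap matrix must be square")
    if not np.allclose(gap, gap.T):
        raise ValueError("gap matrix must be symmetric (coupling is bidirectional)")
    if np.any(np.diag(gap) != 0):
        raise ValueError("gap matrix must have a zero diagonal")
    if np.any(gap < 0):
        raise ValueError("gap conductances must be nonnegative")
    return gap


def gap_currents(v: np.ndarray, gap: np.ndarray) -> np.ndarray:
    """Gap-junction coupling term c_j = sum_i g_ij (V_i - V_j) in pA.

    The membrane equation applies this as a depolarizing drive toward
    the neighbours (dV_j/dt includes +c_j / C), so current flows from
    the more depolarized neuron of each pair into the other.  Summed
    over the population the pairwise terms cancel exactly.
    """
    v = np.asarray(v, float)
    gap = check_gap_matrix(gap)
    if gap.shape[0] != v.size:
        raise ValueError("dimension mismatch between V and gap matrix")
    return gap @ v - gap.sum(axis=1) * v


def synaptic_currents(
    v: np.ndarray,
    s: np.ndarray,
    syn: np.ndarray,
    g_syn: float = G_SYN,
    e_syn: float = E_SYN,
) -> np.ndarray:
    """Chemical synaptic current I_syn,j = g_syn (sum_i w_ij s_i)(V_j - E_syn) in pA.

    This current enters the membrane equation with a minus sign, so it
    depolarizes the target whenever V_j < E_syn = 0.
    """
    v = np.asarray(v, float)
    s = np.asarray(s, float)
    syn = np.asarray(syn, float)
    if syn.shape != (v.size, v.size) or s.size != v.size:
        raise ValueError("dimension mismatch between V, s and synaptic matrix")
    return g_syn * (s @ syn) * (v - e_syn)


def sample_gap_connectivity(
    n: int, p_gap: float, g_gap: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Erdos-Renyi gap-junction matrix over unordered pairs.

    Each pair {i, j} is independently connected with probability
    ``p_gap``; connected pairs share one junction of conductance
    ``g_gap`` (symmetric entries).
    """
    if not 0.0 <= p_gap <= 1.0:
        raise ValueError("p_gap must be a probability")
    rng = np.random.default_rng(rng)
    upper = np.triu(rng.random((n, n)) < p_gap, k=1)
    gap = np.zeros((n, n))
    gap[upper] = g_gap
    return gap + gap.T


def sample_chemical_connectivity(
    n: int, p_syn: float, w_syn: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Directed chemical weight matrix: each ordered pair i -> j with probability p_syn."""
    if not 0.0 <= p_syn <= 1.0:
        raise ValueError("p_syn must be a probability")
    rng = np.random.default_rng(rng)
    syn = np.where(rng.random((n, n)) < p_syn, w_syn, 0.0)
    np.fill_diagonal(syn, 0.0)
    return syn


def aggregate_coupling(n: int, p: float, strength: float) -> float:
    """Average total coupling input per neuron: G = N p g_gap or W = N p w_syn."""
    return n * p * strength


def per_edge_strength(n: int, p: float, aggregate: float) -> float:
    """Per-edge strength realizing a target aggregate coupling (inverse of above)."""
    if p <= 0 or n <= 0:
        raise ValueError("per-edge strength undefined for p = 0 or empty population")
    return aggregate / (n * p)


def truncated_normal(
    mean: float,
    sd: float,
    size: int,
    rng: np.random.Generator,
    floor: float | None = None,
) -> np.ndarray:
    """Normal draw truncated at mean +/- 3 SD, optionally floored.

    The stated population dispersions (20% of the mean) occasionally
    produce non-physical values (negative conductances, extreme leak
    reversals); +/- 3 SD truncation keeps >99.7% of the distribution
    intact while excluding those.
    """
    if sd < 0:
        raise ValueError("SD must be nonnegative")
    if sd == 0:
        out = np.full(size, float(mean))
    else:
        out = mean + sd * rng.standard_normal(size)
        for _ in range(100):
            bad = np.abs(out - mean) > 3 * sd
            if not bad.any():
                break
            out[bad] = mean + sd * rng.standard_normal(bad.sum())
    if floor is not None:
        out = np.maximum(out, floor)
    return out


@dataclass
class PopulationSpec:
    """Distributional description of a heterogeneous population.

    ``n_nap`` of the ``n`` neurons carry I_NaP; their leak reversal is
    drawn from N(e_leak_nap_mean, e_leak_nap_sd), the rest from
    N(e_leak_simple_mean, e_leak_simple_sd).  All +/- dispersions are
    one standard deviation.  ``t_hmax`` is in ms.
    """

    n: int = 100
    n_nap: int = 40
    e_leak_nap_mean: float = -74.0
    e_leak_nap_sd: float = 14.8
    e_leak_simple_mean: float = -70.0
    e_leak_simple_sd: float = 14.0
    g_leak_mean: float = 1.0
    g_leak_sd: float = 0.2
    gbar_nap_mean: float = 4.0
    gbar_nap_sd: float = 0.8
    t_hmax: float = 9000.0
    p_gap: float = 0.3
    p_syn: float = 0.1
    g_gap: float = 0.0
    w_syn: float = 0.0
    init_v_sd: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_nap <= self.n:
            raise ValueError("n_nap must satisfy 0 <= n_nap <= n")
        for name in ("e_leak_nap_sd", "e_leak_simple_sd", "g_leak_sd", "gbar_nap_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("p_gap", "p_syn"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")

    @property
    def G(self) -> float:
        return aggregate_coupling(self.n, self.p_gap, self.g_gap)

    @property
    def W(self) -> float:
        return aggregate_coupling(self.n, self.p_syn, self.w_syn)


@dataclass
class Population:
    """A concrete sampled population: per-neuron parameters, initial states, coupling."""

    params: list[NeuronParams]
    states: list[NeuronState]
    gap: np.ndarray
    syn: np.ndarray
    spec: PopulationSpec | None = None
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.params)

    @property
    def has_nap(self) -> np.ndarray:
        return np.array([p.has_nap for p in self.params])

    def scaled_gap(self, factor: float) -> "Population":
        """Copy of this population with every gap conductance scaled by ``factor``."""
        return Population(
            params=self.params,
            states=self.states,
            gap=self.gap * factor,
            syn=self.syn,
            spec=self.spec,
            seed=self.seed,
        )


def sample_population_params(
    spec: PopulationSpec, rng: np.random.Generator | int | None = None
) -> tuple[list[NeuronParams], list[NeuronState]]:
    """Draw per-neuron parameters and randomized initial states.

    The first ``n_nap`` neurons carry I_NaP.  Initial V is drawn around
    each neuron's leak reversal (SD ``init_v_sd``); integrated gates
    start at their steady state for that V and the synaptic gate at 0.
    The settling period of a simulation absorbs residual dependence on
    these initial conditions.
    """
    rng = np.random.default_rng(rng)
    n, n_nap = spec.n, spec.n_nap
    e_leak = np.empty(n)
    e_leak[:n_nap] = truncated_normal(spec.e_leak_nap_mean, spec.e_leak_nap_sd, n_nap, rng)
    e_leak[n_nap:] = truncated_normal(
        spec.e_leak_simple_mean, spec.e_leak_simple_sd, n - n_nap, rng
    )
    g_leak = truncated_normal(spec.g_leak_mean, spec.g_leak_sd, n, rng, floor=0.0)
    gbar_nap = truncated_normal(spec.gbar_nap_mean, spec.gbar_nap_sd, n_nap, rng, floor=0.0)

    params: list[NeuronParams] = []
    for i in range(n):
        params.append(
            NeuronParams(
                e_leak=float(e_leak[i]),
                g_leak=float(g_leak[i]),
                gbar_nap=float(gbar_nap[i]) if i < n_nap else 0.0,
                has_nap=i < n_nap,
                t_hmax=spec.t_hmax,
            )
        )
    v0 = e_leak + spec.init_v_sd * rng.standard_normal(n)
    states = [NeuronState.at_rest(float(v)) for v in v0]
    return params, states


def sample_population(
    spec: PopulationSpec, seed: int | np.random.Generator | None = None
) -> Population:
    """Sample parameters, initial states and both connectivity matrices."""
    rng = np.random.default_rng(seed)
    params, states = sample_population_params(spec, rng)
    gap = sample_gap_connectivity(spec.n, spec.p_gap, spec.g_gap, rng)
    syn = sample_chemical_connectivity(spec.n, spec.p_syn, spec.w_syn, rng)
    return Population(
        params=params,
        states=states,
        gap=gap,
        syn=syn,
        spec=spec,
        seed=seed if isinstance(seed, int) else None,
    )


def connectivity_edge_table(matrix: np.ndarray) -> list[tuple[int, int, float]]:
    """(i, j, strength) rows for every nonzero entry — plain-text audit format."""
    ii, jj = np.nonzero(matrix)
    return [(int(i), int(j), float(matrix[i, j])) for i, j in zip(ii, jj)]
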