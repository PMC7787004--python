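"""Fixed-step integration of coupled neuron networks.

The coupled membrane/gating/synaptic ODE system is advanced with a
fixed-step second-order Runge-Kutta (midpoint) scheme.  The inner loop
is a numba-compiled kernel over flat per-neuron parameter arrays and
sparse edge lists; spikes are detected online as upward crossings of a
threshold with a short refractory guard.

Times inside the engine are milliseconds; the analysis layer converts
to seconds where burst periods and frequencies are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from numba import njit

from .neuron import NeuronParams, NeuronState, params_arrays
from .network import E_SYN, G_SYN, Population, PopulationSpec, sample_population

__all__ = [
    "SimConfig",
    "SpikeTrain",
    "Trajectory",
    "Network",
    "two_cell_network",
    "integrate",
    "detect_spikes",
    "run_two_cell",
    "run_population",
    "TwoCellResult",
]


@dataclass
class SimConfig:
    """Simulation control.

    ``duration`` is the total simulated time in seconds; the analysis
    window is [``settle``, ``duration``].  ``dt`` and ``record_dt`` are
    in ms.  ``record_dt`` controls the stride of the stored voltage
    traces (the integration step is always ``dt``).
    """

    dt: float = 0.05
    duration: float = 120.0
    settle: float = 20.0
    record_dt: float = 1.0
    record_v: bool = True
    spike_threshold: float = -20.0
    refractory: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.settle < self.duration:
            raise ValueError("settling must be shorter than the total duration")
        if self.record_dt < self.dt:
            self.record_dt = self.dt

    @property
    def analysis_window_ms(self) -> tuple[float, float]:
        return self.settle * 1000.0, self.duration * 1000.0


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) of one neuron."""

    neuron_id: int
    times: np.ndarray  # ms, strictly increasing

    def __len__(self) -> int:
        return self.times.size

    def in_window(self, t0_ms: float, t1_ms: float) -> np.ndarray:
        t = self.times
        return t[(t >= t0_ms) & (t < t1_ms)]


@dataclass
class Trajectory:
    """Result of one integration: recorded voltages and spike trains."""

    t: np.ndarray  # ms, recorded grid (strictly increasing)
    v: np.ndarray | None  # (len(t), N) mV, None when recording is off
    spikes: list[SpikeTrain]
    config: SimConfig
    gates: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.spikes)

    def spike_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (times_ms, neuron_ids) arrays over all neurons, time-sorted."""
        times = np.concatenate([st.times for st in self.spikes]) if self.spikes else np.empty(0)
        ids = np.concatenate(
            [np.full(len(st), st.neuron_id) for st in self.spikes]
        ) if self.spikes else np.empty(0, int)
        order = np.argsort(times, kind="stable")
        return times[order], ids[order].astype(int)


@dataclass
class Network:
    """A concrete network: per-neuron parameters, initial states, coupling matrices."""

    params: list[NeuronParams]
    states: list[NeuronState]
    gap: np.ndarray
    syn: np.ndarray

    @property
    def n(self) -> int:
        return len(self.params)

    @classmethod
    def from_population(cls, pop: Population) -> "Network":
        return cls(params=pop.params, states=pop.states, gap=pop.gap, syn=pop.syn)


def two_cell_network(
    a: NeuronParams,
    b: NeuronParams,
    coupling: str = "none",
    g_gap: float = 0.0,
    w_syn: float = 0.0,
    direction: tuple[int, int] = (0, 1),
) -> Network:
    """Two neurons coupled by one gap junction or one chemical synapse.

    ``coupling`` is 'none', 'gap' (bidirectional, conductance
    ``g_gap``) or 'chemical' (unidirectional source->target along
    ``direction``, weight ``w_syn``).
    """
    gap = np.zeros((2, 2))
    syn = np.zeros((2, 2))
    if coupling == "gap":
        gap[0, 1] = gap[1, 0] = g_gap
    elif coupling == "chemical":
        src, dst = direction
        syn[src, dst] = w_syn
    elif coupling != "none":
        raise ValueError(f"unknown coupling mode {coupling!r}")
    states = [NeuronState.at_rest(a.e_leak), NeuronState.at_rest(b.e_leak)]
    return Network(params=[a, b], states=states, gap=gap, syn=syn)


@njit(cache=True, fastmath=True, error_model="numpy")
def _deriv(
    v, h_na, h_nap, m_k, s,
    c, g_na, g_k, g_l, g_nap, e_na, e_k, e_l, t_hmax,
    gap_src, gap_dst, gap_g, syn_src, syn_dst, syn_w, g_syn, e_syn,
    tau_floor,
    i_cpl, syn_in,
    dv, dh_na, dh_nap, dm_k, ds,
):
    n = v.size
    for j in range(n):
        i_cpl[j] = 0.0
        syn_in[j] = 0.0
    for e in range(gap_src.size):
        i = gap_src[e]
        j = gap_dst[e]
        i_cpl[j] += gap_g[e] * (v[i] - v[j])
    for e in range(syn_src.size):
        syn_in[syn_dst[e]] += syn_w[e] * s[syn_src[e]]
    for j in range(n):
        vj = v[j]
        m_na = 1.0 / (1.0 + math.exp(-(vj + 42.5) / 6.5))
        m_nap = 1.0 / (1.0 + math.exp(-(vj + 52.0) / 3.2))
        i_na = g_na[j] * m_na * m_na * m_na * h_na[j] * (vj - e_na[j])
        i_nap = g_nap[j] * m_nap * h_nap[j] * (vj - e_na[j])
        mk = m_k[j]
        i_k = g_k[j] * mk * mk * mk * mk * (vj - e_k[j])
        i_l = g_l[j] * (vj - e_l[j])
        i_syn = g_syn * syn_in[j] * (vj - e_syn)
        dv[j] = (-(i_na + i_nap + i_k + i_l + i_syn) + i_cpl[j]) / c[j]

        # gate time constants are floored at the integration step: far from
        # the half-voltage the cosh profile collapses below dt, where the
        # gate is effectively instantaneous at its steady state but the
        # explicit update would be unstable
        x = (vj + 65.5) / 12.8
        tau = 35.2 / (0.5 * (math.exp(x) + math.exp(-x)))
        if tau < tau_floor:
            tau = tau_floor
        dh_na[j] = (1.0 / (1.0 + math.exp((vj + 65.5) / 10.2)) - h_na[j]) / tau
        x = (vj + 57.0) / 8.0
        tau = t_hmax[j] / (0.5 * (math.exp(x) + math.exp(-x)))
        if tau < tau_floor:
            tau = tau_floor
        dh_nap[j] = (1.0 / (1.0 + math.exp((vj + 57.0) / 5.0)) - h_nap[j]) / tau
        x = (vj + 34.5) / 10.0
        tau = 10.0 / (0.5 * (math.exp(x) + math.exp(-x)))
        if tau < tau_floor:
            tau = tau_floor
        dm_k[j] = (1.0 / (1.0 + math.exp(-(vj + 34.5) / 5.0)) - m_k[j]) / tau
        s_inf = 1.0 / (1.0 + math.exp(-(vj + 20.0) / 2.0))
        ds[j] = (s_inf * (1.0 - s[j]) - s[j]) / 15.0


@njit(cache=True)
def _scan_divergence(v):
    # NaN-safe range scan; deliberately compiled without fastmath so the
    # comparisons survive (fastmath assumes no NaNs and may elide them)
    for j in range(v.size):
        if not (-500.0 < v[j] < 500.0):
            return j
    return -1


@njit(cache=True, fastmath=True, error_model="numpy")
def _rk2_loop(
    v, h_na, h_nap, m_k, s,
    c, g_na, g_k, g_l, g_nap, e_na, e_k, e_l, t_hmax,
    gap_src, gap_dst, gap_g, syn_src, syn_dst, syn_w, g_syn, e_syn,
    dt, n_steps, rec_stride, rec_v,
    thr, refr_ms, spike_t, spike_id,
):
    n = v.size
    i_cpl = np.zeros(n)
    syn_in = np.zeros(n)
    k1v = np.zeros(n); k1a = np.zeros(n); k1b = np.zeros(n); k1c = np.zeros(n); k1d = np.zeros(n)
    k2v = np.zeros(n); k2a = np.zeros(n); k2b = np.zeros(n); k2c = np.zeros(n); k2d = np.zeros(n)
    mv = np.zeros(n); ma = np.zeros(n); mb = np.zeros(n); mc = np.zeros(n); md = np.zeros(n)
    last_spike = np.full(n, -1e30)
    n_spikes = 0
    max_spikes = spike_t.size
    rec_rows = rec_v.shape[0]

    for step in range(n_steps):
        _deriv(
            v, h_na, h_nap, m_k, s,
            c, g_na, g_k, g_l, g_nap, e_na, e_k, e_l, t_hmax,
            gap_src, gap_dst, gap_g, syn_src, syn_dst, syn_w, g_syn, e_syn,
            dt, i_cpl, syn_in, k1v, k1a, k1b, k1c, k1d,
        )
        for j in range(n):
            mv[j] = v[j] + 0.5 * dt * k1v[j]
            ma[j] = h_na[j] + 0.5 * dt * k1a[j]
            mb[j] = h_nap[j] + 0.5 * dt * k1b[j]
            mc[j] = m_k[j] + 0.5 * dt * k1c[j]
            md[j] = s[j] + 0.5 * dt * k1d[j]
        _deriv(
            mv, ma, mb, mc, md,
            c, g_na, g_k, g_l, g_nap, e_na, e_k, e_l, t_hmax,
            gap_src, gap_dst, gap_g, syn_src, syn_dst, syn_w, g_syn, e_syn,
            dt, i_cpl, syn_in, k2v, k2a, k2b, k2c, k2d,
        )
        t_next = (step + 1) * dt
        for j in range(n):
            v_prev = v[j]
            v[j] = v_prev + dt * k2v[j]
            # clamp gating variables into [0, 1] (floating-point overshoot)
            x = h_na[j] + dt * k2a[j]
            h_na[j] = 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)
            x = h_nap[j] + dt * k2b[j]
            h_nap[j] = 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)
            x = m_k[j] + dt * k2c[j]
            m_k[j] = 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)
            x = s[j] + dt * k2d[j]
            s[j] = 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)
            if v_prev < thr <= v[j] and t_next - last_spike[j] >= refr_ms:
                last_spike[j] = t_next
                if n_spikes < max_spikes:
                    spike_t[n_spikes] = t_next
                    spike_id[n_spikes] = j
                    n_spikes += 1
                else:
                    return n_spikes, -2, t_next
        if (step + 1) % 100 == 0:
            bad = _scan_divergence(v)
            if bad >= 0:
                return n_spikes, bad, t_next
        if rec_stride > 0 and (step + 1) % rec_stride == 0:
            row = (step + 1) // rec_stride - 1
            if row < rec_rows:
                for j in range(n):
                    rec_v[row, j] = v[j]
    bad = _scan_divergence(v)
    if bad >= 0:
        return n_spikes, bad, n_steps * dt
    return n_spikes, -1, 0.0


def _edges(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    src, dst = np.nonzero(matrix)
    return src.astype(np.int64), dst.astype(np.int64), matrix[src, dst].astype(float)


def integrate(network: Network, config: SimConfig) -> Trajectory:
    """Advance the coupled system and record voltages and spikes.

    Deterministic for a given network and config.  Aborts with a
    diagnostic naming the first neuron whose state turns non-finite.
    """
    n = network.n
    p = params_arrays(network.params)
    v = np.array([st.v for st in network.states], float)
    h_na = np.array([st.h_na for st in network.states], float)
    h_nap = np.array([st.h_nap for st in network.states], float)
    m_k = np.array([st.m_k for st in network.states], float)
    s = np.array([st.s for st in network.states], float)

    # the kernel is compiled with fast-math arithmetic, under which NaN does
    # not propagate dependably; reject a non-finite *initial* state here
    # (mid-run divergence passes through large finite values first, which the
    # kernel's periodic range scan reports)
    bad = np.flatnonzero(~((v > -500.0) & (v < 500.0)))
    if bad.size:
        raise RuntimeError(
            f"non-finite or out-of-range membrane potential in neuron {bad[0]} "
            f"at t = 0.000 ms"
        )

    gap_src, gap_dst, gap_g = _edges(np.asarray(network.gap, float))
    syn_src, syn_dst, syn_w = _edges(np.asarray(network.syn, float))

    dt = config.dt
    n_steps = int(round(config.duration * 1000.0 / dt))
    if config.record_v:
        rec_stride = max(1, int(round(config.record_dt / dt)))
        rec_rows = n_steps // rec_stride
        rec_v = np.empty((rec_rows, n), np.float32)
    else:
        rec_stride = 0
        rec_v = np.empty((0, n), np.float32)

    # spike buffer sized for sustained 250 Hz per neuron; the refractory
    # guard bounds the true worst case at 1/refractory, so retry with the
    # hard bound if a pathological population overflows the first guess
    for rate_cap in (250.0, 1000.0 / config.refractory):
        max_spikes = int(n * config.duration * rate_cap) + 1000
        spike_t = np.empty(max_spikes)
        spike_id = np.empty(max_spikes, np.int64)
        v_run, h_na_run = v.copy(), h_na.copy()
        h_nap_run, m_k_run, s_run = h_nap.copy(), m_k.copy(), s.copy()
        n_spikes, status, t_bad = _rk2_loop(
            v_run, h_na_run, h_nap_run, m_k_run, s_run,
            p["c"], p["gbar_na"], p["gbar_k"], p["g_leak"], p["g_nap"],
            p["e_na"], p["e_k"], p["e_leak"], p["t_hmax"],
            gap_src, gap_dst, gap_g, syn_src, syn_dst, syn_w, G_SYN, E_SYN,
            dt, n_steps, rec_stride, rec_v,
            config.spike_threshold, config.refractory, spike_t, spike_id,
        )
        if status != -2:
            break
    if status == -2:
        raise RuntimeError(f"spike buffer overflow at t = {t_bad:.1f} ms")
    if status >= 0:
        raise RuntimeError(
            f"integration diverged: non-finite membrane potential in neuron {status} "
            f"at t = {t_bad:.3f} ms"
        )

    trains = []
    st_, si_ = spike_t[:n_spikes], spike_id[:n_spikes]
    for j in range(n):
        trains.append(SpikeTrain(neuron_id=j, times=st_[si_ == j].copy()))
    if rec_stride > 0:
        t_rec = dt * rec_stride * np.arange(1, rec_v.shape[0] + 1)
    else:
        t_rec = np.empty(0)
        rec_v = None
    return Trajectory(t=t_rec, v=rec_v, spikes=trains, config=config)


def detect_spikes(
    t_ms: np.ndarray,
    v: np.ndarray,
    threshold: float = -20.0,
    refractory_ms: float = 2.0,
    neuron_id: int = 0,
) -> SpikeTrain:
    """Offline spike detector on a uniformly sampled voltage trace.

    A spike is an upward crossing of ``threshold``; re-triggers within
    ``refractory_ms`` are suppressed.  The online detector inside the
    integration kernel applies the identical rule at full step
    resolution.
    """
    v = np.asarray(v, float)
    t_ms = np.asarray(t_ms, float)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = []
    last = -np.inf
    for i in up:
        if t_ms[i] - last >= refractory_ms:
            times.append(t_ms[i])
            last = t_ms[i]
    return SpikeTrain(neuron_id=neuron_id, times=np.asarray(times))


@dataclass
class TwoCellResult:
    """Per-neuron summary of a two-cell run (regime, frequency, resting potential)."""

    trajectory: Trajectory
    regimes: tuple[str, str]
    frequencies: tuple[float | None, float | None]
    resting_potentials: tuple[float, float]
    burst_ratio: tuple[int, int] | None

    def summary(self) -> dict:
        return {
            "regimes": self.regimes,
            "frequencies_hz": self.frequencies,
            "resting_potentials_mv": self.resting_potentials,
            "burst_ratio": self.burst_ratio,
        }


def run_two_cell(
    a: NeuronParams,
    b: NeuronParams,
    coupling: str = "none",
    g_gap: float = 0.0,
    w_syn: float = 0.0,
    direction: tuple[int, int] = (0, 1),
    config: SimConfig | None = None,
) -> TwoCellResult:
    """Integrate a coupled pair and summarize per-neuron regime, frequency,
    resting potential and the burst-count ratio (analysis window only)."""
    from . import analysis

    if config is None:
        config = SimConfig(duration=120.0, settle=20.0)
    net = two_cell_network(a, b, coupling=coupling, g_gap=g_gap, w_syn=w_syn, direction=direction)
    traj = integrate(net, config)
    t0, t1 = config.analysis_window_ms

    regimes, freqs, rests, series = [], [], [], []
    for j in (0, 1):
        train = SpikeTrain(j, traj.spikes[j].in_window(t0, t1))
        bs = analysis.single_neuron_bursts(train, t_ms=traj.t, v=traj.v[:, j])
        regime = analysis.classify_regime(train, t_ms=traj.t, v=traj.v[:, j])
        regimes.append(regime)
        freqs.append(bs.frequency)
        series.append(bs)
        rests.append(analysis.resting_potential(traj.t, traj.v[:, j], train, regime, window_ms=(t0, t1)))
    try:
        ratio = analysis.burst_ratio(series[0], series[1])
    except ValueError:
        ratio = None
    return TwoCellResult(
        trajectory=traj,
        regimes=(regimes[0], regimes[1]),
        frequencies=(freqs[0], freqs[1]),
        resting_potentials=(rests[0], rests[1]),
        burst_ratio=ratio,
    )


def run_population(
    spec: PopulationSpec,
    config: SimConfig | None = None,
    seed: int | None = None,
    population: Population | None = None,
):
    """Sample (or reuse) a population, integrate it and bin the rate.

    Returns ``(trajectory, activity)`` where ``activity`` is the
    100-ms-binned population rate in spikes per neuron per second over
    the analysis window.
    """
    from . import analysis

    if config is None:
        config = SimConfig(duration=100.0, settle=40.0)
    if population is None:
        population = sample_population(spec, seed if seed is not None else config.seed)
    traj = integrate(Network.from_population(population), config)
    t0, t1 = config.analysis_window_ms
    activity = analysis.population_rate(traj, n=population.n, window_ms=(t0, t1))
    return traj, activity
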