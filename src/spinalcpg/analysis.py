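"""Burst detection, regime classification and parameter sweeps.

Single neurons are labelled silent / bursting / tonic from their spike
trains.  Population activity is summarized as the 100-ms-binned rate in
spikes per neuron per second; populational bursts are detected with a
two-pass procedure that sets the onset threshold at 30% of the mean
burst amplitude, and each simulation is assigned one of four stability
classes: no populational activity, low-amplitude/unstable, stable
bursting, or tonic.  On top of these sit the sweep drivers: the (G, W)
regime map over aggregate electrical vs chemical coupling, the
(gbar_NaP, N_NaP) frequency/amplitude curves, and the gap-junction
block comparison (a carbenoxolone analogue: every gap conductance
scaled down by a fixed fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .engine import SimConfig, SpikeTrain, Trajectory
from .network import Population, PopulationSpec, sample_population

__all__ = [
    "BurstSeries",
    "PopulationActivity",
    "segment_bursts",
    "single_neuron_bursts",
    "classify_regime",
    "resting_potential",
    "population_rate",
    "detect_population_bursts",
    "classify_population_state",
    "burst_ratio",
    "synchrony_index",
    "SweepResult",
    "sweep_gw",
    "sweep_gnap",
    "carbenoxolone_compare",
    "analyze_population_run",
]

#: Population stability classes.
LABEL_NONE = "none"
LABEL_UNSTABLE = "low/unstable"
LABEL_STABLE = "stable bursting"
LABEL_TONIC = "tonic"

#: Stability criteria: minimum mean burst amplitude (spikes/neuron/s) and
#: maximum coefficient of variation of the burst period.
MIN_STABLE_AMPLITUDE = 10.0
MAX_PERIOD_CV = 0.5
ONSET_THRESHOLD_FRACTION = 0.3


@dataclass
class BurstSeries:
    """Burst onsets (s) and per-burst peak amplitudes.

    The period is the onset-to-onset difference and the frequency its
    reciprocal; both are undefined (None) with fewer than two bursts,
    mirroring the N/A entries of tonic and silent neurons.
    """

    onsets: np.ndarray  # s, strictly increasing
    amplitudes: np.ndarray | None = None  # spikes/neuron/s for populational bursts
    threshold: float | None = None  # onset threshold actually used (populational)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, float)
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("burst onsets must be strictly increasing")

    @property
    def n_bursts(self) -> int:
        return self.onsets.size

    @property
    def periods(self) -> np.ndarray:
        return np.diff(self.onsets)

    @property
    def mean_period(self) -> float | None:
        return float(self.periods.mean()) if self.onsets.size >= 2 else None

    @property
    def period_sd(self) -> float | None:
        return float(self.periods.std(ddof=0)) if self.onsets.size >= 3 else None

    @property
    def period_cv(self) -> float | None:
        if self.onsets.size < 3 or self.mean_period == 0:
            return None
        return self.period_sd / self.mean_period

    @property
    def frequency(self) -> float | None:
        """Hz; reciprocal of the mean onset-to-onset period."""
        mp = self.mean_period
        return 1.0 / mp if mp else None

    @property
    def amplitude_mean(self) -> float | None:
        if self.amplitudes is None or len(self.amplitudes) == 0:
            return None
        return float(np.mean(self.amplitudes))

    @property
    def amplitude_sd(self) -> float | None:
        if self.amplitudes is None or len(self.amplitudes) == 0:
            return None
        return float(np.std(self.amplitudes, ddof=0))


@dataclass
class PopulationActivity:
    """Binned population rate in spikes per neuron per second."""

    t: np.ndarray  # s, bin centers
    rate: np.ndarray  # spikes / (N * s)
    bin_ms: float
    n: int

    @property
    def mean_rate(self) -> float:
        return float(self.rate.mean()) if self.rate.size else 0.0


def segment_bursts(
    times_ms: np.ndarray,
    gap_ms: float | None = None,
    merge_fraction: float = 0.35,
    t_ms: np.ndarray | None = None,
    v: np.ndarray | None = None,
    depol_gap_mv: float = -55.0,
) -> list[np.ndarray]:
    """Partition a sorted spike train (ms) into bursts.

    Two passes.  First, spikes separated by no more than the gap
    threshold (default max(300 ms, 3 x median ISI)) form clusters; the
    median term merges slow regular spiking — where the median ISI is
    itself long — into a single "burst", which the regime classifier
    then reads as tonic.  Second, adjacent clusters are merged when the
    quiescent gap between them is shorter than ``merge_fraction`` of
    the mean onset-to-onset interval: conditional bursters can emit a
    burst as a doublet of spike clusters separated by a pause that is
    short on the scale of the slow I_NaP-recovery cycle, and such a
    doublet is one burst of the underlying rhythm, not two.  (The mean,
    not the median, sets the scale: with strict doublets half the
    onset intervals are the short intra-doublet pause itself.)  When
    every gap qualifies — a uniform high-duty-cycle rhythm, not a
    doublet pattern — nothing is merged.

    When the voltage trace is supplied (``t_ms``, ``v``), clusters
    separated by a *depolarized* pause are also merged: if the membrane
    potential never falls below ``depol_gap_mv`` between two clusters,
    the neuron never returned toward rest and the pause is a
    within-burst plateau (e.g. a driven burst briefly interrupted near
    depolarization block), not an interburst interval.
    """
    t = np.asarray(times_ms, float)
    if t.size == 0:
        return []
    if t.size == 1:
        return [t]
    isi = np.diff(t)
    if np.any(isi < 0):
        raise ValueError("spike times must be sorted")
    if gap_ms is None:
        gap_ms = max(300.0, 3.0 * float(np.median(isi)))
    breaks = np.flatnonzero(isi > gap_ms)
    bursts = np.split(t, breaks + 1)
    if v is not None and len(bursts) >= 2:
        t_ms = np.asarray(t_ms, float)
        v = np.asarray(v, float)
        merged: list[np.ndarray] = [bursts[0]]
        for b in bursts[1:]:
            in_gap = (t_ms > merged[-1][-1]) & (t_ms < b[0])
            if in_gap.any() and v[in_gap].min() > depol_gap_mv:
                merged[-1] = np.concatenate([merged[-1], b])
            else:
                merged.append(b)
        bursts = merged
    if merge_fraction <= 0:
        return bursts
    while len(bursts) >= 3:
        onsets = np.array([b[0] for b in bursts])
        offsets = np.array([b[-1] for b in bursts])
        gaps = onsets[1:] - offsets[:-1]
        cutoff = merge_fraction * float(np.mean(np.diff(onsets)))
        small = gaps < cutoff
        if not small.any() or small.all():
            break
        merged: list[np.ndarray] = [bursts[0]]
        for b, is_small in zip(bursts[1:], small):
            if is_small:
                merged[-1] = np.concatenate([merged[-1], b])
            else:
                merged.append(b)
        bursts = merged
    return bursts


def single_neuron_bursts(
    train: SpikeTrain,
    gap_ms: float | None = None,
    t_ms: np.ndarray | None = None,
    v: np.ndarray | None = None,
) -> BurstSeries:
    """Burst statistics of one neuron; onset = first spike of each burst."""
    bursts = segment_bursts(train.times, gap_ms=gap_ms, t_ms=t_ms, v=v)
    onsets = np.array([b[0] for b in bursts]) / 1000.0
    return BurstSeries(onsets=onsets)


def classify_regime(
    train: SpikeTrain,
    gap_ms: float | None = None,
    t_ms: np.ndarray | None = None,
    v: np.ndarray | None = None,
) -> str:
    """Single-neuron label: 'silent' (no spikes), 'bursting' (>= 2 spike
    clusters separated by quiescent gaps) or 'tonic'."""
    if len(train) == 0:
        return "silent"
    bursts = segment_bursts(train.times, gap_ms=gap_ms, t_ms=t_ms, v=v)
    return "bursting" if len(bursts) >= 2 else "tonic"


def resting_potential(
    t_ms: np.ndarray,
    v: np.ndarray,
    train: SpikeTrain,
    regime: str,
    window_ms: tuple[float, float] | None = None,
    tail_s: float = 5.0,
) -> float:
    """Membrane-potential summary matching the tabulated 'resting potential'.

    Silent neurons: mean V over the last ``tail_s`` seconds of the
    window.  Bursting neurons: mean V over the interburst intervals.
    Tonic neurons: mean V over the inter-spike intervals (a few ms
    around each spike excluded).  Averaging the quiescent stretches,
    rather than taking their minima, is what best matches a
    slow-charting "resting" level read off a trace: the interburst
    potential of an I_NaP burster drifts upward as inactivation
    recovers, so its minimum systematically undershoots.
    """
    t_ms = np.asarray(t_ms, float)
    v = np.asarray(v, float)
    if window_ms is not None:
        m = (t_ms >= window_ms[0]) & (t_ms <= window_ms[1])
        t_ms, v = t_ms[m], v[m]
    if regime == "silent" or len(train) < 2:
        mask = t_ms >= t_ms[-1] - tail_s * 1000.0
        return float(v[mask].mean())
    if regime == "bursting":
        bursts = segment_bursts(train.times, t_ms=t_ms, v=v)
        intervals = [(b0[-1], b1[0]) for b0, b1 in zip(bursts[:-1], bursts[1:])]
    else:  # tonic: quiescent stretches between consecutive spikes
        intervals = list(zip(train.times[:-1], train.times[1:]))
    levels = []
    for a, b in intervals:
        m = (t_ms > a + 5.0) & (t_ms < b - 1.0)
        if m.any():
            levels.append(v[m].mean())
    if not levels:
        mask = t_ms >= t_ms[-1] - tail_s * 1000.0
        return float(v[mask].mean())
    return float(np.mean(levels))


def population_rate(
    traj: Trajectory,
    n: int | None = None,
    bin_ms: float = 100.0,
    window_ms: tuple[float, float] | None = None,
) -> PopulationActivity:
    """Averaged histogram of spiking: spikes per neuron per second per 100-ms bin."""
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    if n is None:
        n = traj.n
    times, _ = traj.spike_arrays()
    if window_ms is None:
        window_ms = traj.config.analysis_window_ms
    t0, t1 = window_ms
    n_bins = max(1, int(round((t1 - t0) / bin_ms)))
    edges = t0 + bin_ms * np.arange(n_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    rate = counts / (n * bin_ms / 1000.0)
    centers = (edges[:-1] + edges[1:]) / 2.0 / 1000.0
    return PopulationActivity(t=centers, rate=rate, bin_ms=bin_ms, n=n)


def detect_population_bursts(
    activity: PopulationActivity,
    threshold_fraction: float = ONSET_THRESHOLD_FRACTION,
    min_peak_separation_s: float = 0.5,
    threshold: float | None = None,
) -> BurstSeries:
    """Two-pass populational burst detection.

    Pass 1 locates provisional burst peaks (local maxima above half the
    trace maximum, separated by at least ``min_peak_separation_s``) and
    averages their heights.  Pass 2 places burst onsets at upward
    crossings of ``threshold_fraction`` (30%) of that average burst
    amplitude.  Per-burst amplitude is the rate maximum between
    consecutive onsets.  An explicit ``threshold`` overrides pass 1 —
    the programmatic replacement for manually chosen thresholds on less
    stable simulations.
    """
    rate = activity.rate
    t = activity.t
    if rate.size == 0 or rate.max() <= 0:
        return BurstSeries(onsets=np.empty(0), amplitudes=np.empty(0), threshold=None)
    if threshold is None:
        distance = max(1, int(round(min_peak_separation_s / (activity.bin_ms / 1000.0))))
        peaks, _ = find_peaks(rate, height=0.5 * rate.max(), distance=distance)
        if peaks.size == 0:
            return BurstSeries(onsets=np.empty(0), amplitudes=np.empty(0), threshold=None)
        threshold = threshold_fraction * float(rate[peaks].mean())
    up = np.flatnonzero((rate[:-1] < threshold) & (rate[1:] >= threshold)) + 1
    if up.size == 0:
        return BurstSeries(onsets=np.empty(0), amplitudes=np.empty(0), threshold=threshold)
    onsets = t[up]
    bounds = list(up) + [rate.size]
    amplitudes = np.array([rate[a:b].max() for a, b in zip(bounds[:-1], bounds[1:])])
    return BurstSeries(onsets=onsets, amplitudes=amplitudes, threshold=threshold)


def classify_population_state(
    series: BurstSeries,
    activity: PopulationActivity,
    min_amplitude: float = MIN_STABLE_AMPLITUDE,
    max_period_cv: float = MAX_PERIOD_CV,
) -> str:
    """Four-class stability taxonomy of one population simulation.

    'none' for a quiescent population; 'tonic' for sustained activity
    that never crosses down through the burst threshold; 'low/unstable'
    for mean burst amplitude below ``min_amplitude`` (10 spikes/neuron/s)
    or period coefficient of variation >= ``max_period_cv`` (50%), or
    too few cycles to judge; otherwise 'stable bursting'.
    """
    if activity.mean_rate < 0.5:
        return LABEL_NONE
    if series.n_bursts == 0:
        return LABEL_TONIC if activity.mean_rate >= min_amplitude else LABEL_UNSTABLE
    if series.n_bursts < 3:
        return LABEL_UNSTABLE
    if series.amplitude_mean is not None and series.amplitude_mean < min_amplitude:
        return LABEL_UNSTABLE
    cv = series.period_cv
    if cv is None or cv >= max_period_cv:
        return LABEL_UNSTABLE
    return LABEL_STABLE


def burst_ratio(
    series_a: BurstSeries, series_b: BurstSeries, max_denominator: int = 6
) -> tuple[int, int]:
    """Reduced burst-count ratio M:N of two series over their common window.

    The ratio is taken over complete cycles (onset-to-onset intervals)
    inside the overlap of the two series, which avoids the fencepost
    bias of raw onset counts over a shared window.
    """
    if series_a.n_bursts == 0 or series_b.n_bursts == 0:
        raise ValueError("burst ratio undefined for an empty series")
    t0 = max(series_a.onsets[0], series_b.onsets[0]) - 1e-9
    t1 = min(series_a.onsets[-1], series_b.onsets[-1]) + 1e-9
    ca = int(np.sum((series_a.onsets >= t0) & (series_a.onsets <= t1))) - 1
    cb = int(np.sum((series_b.onsets >= t0) & (series_b.onsets <= t1))) - 1
    if ca <= 0 or cb <= 0:
        raise ValueError("need at least one full cycle of each series in the common window")
    frac = Fraction(ca, cb)
    if max(frac.numerator, frac.denominator) > max_denominator:
        frac = frac.limit_denominator(max_denominator)
    return frac.numerator, frac.denominator


def synchrony_index(
    traj: Trajectory,
    neuron_ids: np.ndarray | list[int] | None = None,
    window_ms: tuple[float, float] | None = None,
    bin_ms: float = 100.0,
) -> float:
    """Mean pairwise correlation of binned spike counts.

    Pairs involving neurons with constant (usually zero) binned counts
    carry no correlation information and are excluded.
    """
    if window_ms is None:
        window_ms = traj.config.analysis_window_ms
    t0, t1 = window_ms
    ids = range(traj.n) if neuron_ids is None else neuron_ids
    edges = np.arange(t0, t1 + bin_ms / 2, bin_ms)
    counts = []
    for j in ids:
        c, _ = np.histogram(traj.spikes[j].in_window(t0, t1), bins=edges)
        if c.std() > 0:
            counts.append(c)
    if len(counts) < 2:
        return float("nan")
    corr = np.corrcoef(np.asarray(counts, float))
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


def analyze_population_run(
    traj: Trajectory,
    activity: PopulationActivity,
    threshold: float | None = None,
) -> tuple[str, BurstSeries]:
    """Label one population simulation and return its burst series."""
    series = detect_population_bursts(activity, threshold=threshold)
    return classify_population_state(series, activity), series


@dataclass
class SweepResult:
    """Tidy table of a parameter sweep plus its provenance."""

    table: pd.DataFrame
    spec: PopulationSpec
    seed: int | None = None

    def cell(self, **coords) -> pd.Series:
        m = np.ones(len(self.table), bool)
        for k, val in coords.items():
            m &= np.isclose(self.table[k], val)
        rows = self.table[m]
        if len(rows) != 1:
            raise KeyError(f"expected exactly one sweep cell at {coords}, found {len(rows)}")
        return rows.iloc[0]


def _run_fixed_population(pop: Population, config: SimConfig) -> tuple[str, BurstSeries, PopulationActivity]:
    from .engine import run_population  # local alias for clarity

    traj, activity = run_population(pop.spec, config=config, population=pop)
    label, series = analyze_population_run(traj, activity)
    return label, series, activity


def sweep_gw(
    spec: PopulationSpec,
    g_values: np.ndarray | list[float],
    w_values: np.ndarray | list[float],
    config: SimConfig | None = None,
    seed: int | None = None,
    stop_when=None,
) -> SweepResult:
    """Regime map over aggregate electrical (G, nS) and chemical (W) coupling.

    One population (parameters, topology, initial conditions) is
    sampled once under ``seed`` with unit per-edge strengths; every
    (G, W) cell rescales the same matrices via the aggregate-coupling
    inverse, so the sweep varies only connection strengths.
    ``stop_when(row)`` can abort the sweep early (e.g., threshold
    searches along one axis).
    """
    if config is None:
        config = SimConfig(duration=80.0, settle=20.0)
    base_spec = replace(spec, g_gap=1.0, w_syn=1.0)
    pop = sample_population(base_spec, seed)
    rows = []
    done = False
    for g_total in g_values:
        if done:
            break
        g_edge = g_total / (spec.n * spec.p_gap) if spec.p_gap > 0 else 0.0
        for w_total in w_values:
            w_edge = w_total / (spec.n * spec.p_syn) if spec.p_syn > 0 else 0.0
            cell_pop = Population(
                params=pop.params,
                states=pop.states,
                gap=pop.gap * g_edge,
                syn=pop.syn * w_edge,
                spec=replace(spec, g_gap=g_edge, w_syn=w_edge),
                seed=pop.seed,
            )
            label, series, activity = _run_fixed_population(cell_pop, config)
            stable = label == LABEL_STABLE
            row = {
                "G": float(g_total),
                "W": float(w_total),
                "g_gap": g_edge,
                "w_syn": w_edge,
                "label": label,
                "frequency_hz": series.frequency if stable else np.nan,
                "amplitude": series.amplitude_mean if stable else np.nan,
                "period_sd_s": series.period_sd if stable else np.nan,
                "mean_rate": activity.mean_rate,
            }
            rows.append(row)
            if stop_when is not None and stop_when(row):
                done = True
                break
    return SweepResult(table=pd.DataFrame(rows), spec=spec, seed=seed)


def sweep_gnap(
    spec: PopulationSpec,
    gnap_values: np.ndarray | list[float],
    n_nap_values: np.ndarray | list[int] = (20, 30, 40),
    config: SimConfig | None = None,
    seed: int | None = None,
) -> SweepResult:
    """Populational frequency/amplitude vs mean I_NaP conductance and N_NaP.

    The electrical coupling is fixed (default spec.g_gap, nominally
    0.06 nS); each cell resamples the population under the same seed so
    that cells differ only through gbar_NaP and the subpopulation size.
    """
    if config is None:
        config = SimConfig(duration=80.0, settle=20.0)
    rows = []
    for n_nap in n_nap_values:
        for gnap in gnap_values:
            cell_spec = replace(spec, n_nap=int(n_nap), gbar_nap_mean=float(gnap))
            pop = sample_population(cell_spec, seed)
            label, series, activity = _run_fixed_population(pop, config)
            stable = label == LABEL_STABLE
            rows.append(
                {
                    "gbar_nap": float(gnap),
                    "n_nap": int(n_nap),
                    "label": label,
                    "frequency_hz": series.frequency if stable else np.nan,
                    "amplitude": series.amplitude_mean if stable else np.nan,
                    "mean_rate": activity.mean_rate,
                }
            )
    return SweepResult(table=pd.DataFrame(rows), spec=spec, seed=seed)


def carbenoxolone_compare(
    spec: PopulationSpec,
    reduction: float = 0.5,
    n_runs: int = 5,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gap-junction block analogue: scale every gap conductance by (1 - reduction).

    For each of ``n_runs`` parameter randomizations the same population
    is simulated at baseline and reduced coupling; frequencies are in
    Hz and amplitudes are normalized to the baseline of the same run.
    Runs whose baseline is not stable bursting are flagged.
    """
    if config is None:
        config = SimConfig(duration=60.0, settle=20.0)
    if not 0.0 <= reduction <= 1.0:
        raise ValueError("reduction must be a fraction in [0, 1]")
    base_seed = 0 if seed is None else seed
    rows = []
    for k in range(n_runs):
        pop = sample_population(spec, base_seed + k)
        label0, series0, _ = _run_fixed_population(pop, config)
        label1, series1, _ = _run_fixed_population(pop.scaled_gap(1.0 - reduction), config)
        amp0 = series0.amplitude_mean
        amp1 = series1.amplitude_mean
        rows.append(
            {
                "run": k,
                "seed": base_seed + k,
                "baseline_label": label0,
                "reduced_label": label1,
                "baseline_frequency_hz": series0.frequency,
                "reduced_frequency_hz": series1.frequency,
                "baseline_amplitude_norm": 1.0 if amp0 else np.nan,
                "reduced_amplitude_norm": (amp1 / amp0) if (amp0 and amp1 is not None) else np.nan,
                "baseline_stable": label0 == LABEL_STABLE,
            }
        )
    return pd.DataFrame(rows)
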