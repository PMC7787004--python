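# Model and methods

## The model

`spinalcpg` simulates heterogeneous networks of single-compartment
Hodgkin–Huxley neurons of two kinds: conditional bursters carrying a
persistent (slowly inactivating) sodium current, I_NaP, and simple
spiking neurons without it.  The membrane equation of a burster is

    C dV/dt = −I_Na − I_NaP − I_K − I_L − I_Syn + I_Gap,

with the I_NaP term absent in simple neurons.  Currents (nS·mV = pA):

    I_Na  = ḡ_Na · m∞Na(V)³ · h_Na · (V − E_Na)
    I_NaP = ḡ_NaP · m∞NaP(V) · h_NaP · (V − E_Na)
    I_K   = ḡ_K · m_K⁴ · (V − E_K)
    I_L   = g_L · (V − E_L)

Gating variables follow first-order relaxation dx/dt = (x∞(V) − x)/τ_x(V)
with Boltzmann steady states and cosh-reciprocal time constants;
activation of both sodium currents is instantaneous (evaluated
algebraically each step, never integrated).  Half-voltages, slopes and
peak time constants are listed in `spinalcpg.neuron.KINETICS`; the peak
h_NaP time constant `t_hmax` (default 9 s) sets the slow time scale of
bursting.  Standard constants: C = 40 pF, ḡ_Na = 80 nS, ḡ_K = 100 nS,
g_L = 1 nS, E_Na = 55 mV, E_K = −80 mV.  Units are mV, ms, nS, pF, pA
throughout, so pA/pF = mV/ms closes the membrane equation; `t_hmax`
values quoted in seconds in configuration files are converted to ms at
load.

A neuron's operating regime is set by its leak reversal E_L: a burster
is silent below roughly −71 mV, bursts intrinsically between about −71
and −65 mV (0.05–0.45 Hz), and spikes tonically above; a simple neuron
switches from silent to tonic near −59.5 mV.

### Coupling

Electrical synapses (gap junctions) are bidirectional and ohmic:
neuron j receives Σ_i g_Gap,ij (V_i − V_j), which drives V_j toward its
neighbours.  (The membrane equation applies this term with a positive
sign; the equivalent formulation with a subtracted coupling current of
the opposite sign convention describes the same physics.)  The matrix
is symmetric with zero diagonal; summed over the population the
pairwise terms cancel exactly, which the tests assert.

Chemical synapses are unidirectional and AMPA-like:
I_Syn,j = g_Syn (Σ_i w_ij s_i)(V_j − E_Syn) with g_Syn = 1 nS and
E_Syn = 0, so the current is depolarizing for any subthreshold target.
The presynaptic gate obeys

    τ_s ds/dt = α_s · s∞(V) · (1 − s) − s,
    s∞(V) = 1 / (1 + exp(−(V + 20)/2)),

with α_s = 1 (dimensionless) and τ_s = 15 ms.  Under this form a spike
of ~2 ms above the −20 mV half-activation increments s by ~0.1 and the
gate decays with τ_s between spikes, giving a mean gate of ~0.01 per
unit weight for a tonic source — the scale implied by the published
two-cell voltage shifts (a weight-2 synapse from a tonic source shifts
a silent target's resting potential by ~2.5 mV).  The alternative
reading with α_s = 1 ms⁻¹ (rise 15× faster) was rejected because it
saturates the gate, drives two-cell targets into sustained spiking at
tabulated weights, and eliminates the population's stable-bursting
window entirely.

### Population randomization

The default population has N = 100 neurons, of which N_NaP = 40 are
bursters.  Heterogeneity: E_L ~ Normal(−74, 14.8) mV for bursters and
Normal(−70, 14) mV for simple neurons; g_L ~ Normal(1, 0.2) nS;
ḡ_NaP ~ Normal(4, 0.8) nS.  The ± dispersions are one standard
deviation; draws are truncated at mean ± 3 SD and conductances floored
at zero, because the 20%-of-mean dispersions otherwise occasionally
produce non-physical values.  Connectivity is Erdős–Rényi: each
unordered pair shares a gap junction with probability p_Gap = 0.3 and
each ordered pair a chemical synapse with probability p_Syn = 0.1
(these probabilities parameterize the coupling statistics measured for
neonatal spinal Shox2 interneurons).  Reciprocal chemical pairs are
allowed; at p = 0.1 they are rare.  Aggregate coupling is summarized as
G = N·p_Gap·g_Gap (nS) and W = N·p_Syn·w_Syn (dimensionless), the
expected total electrical/chemical input per neuron; sweeps specify
(G, W) and derive per-edge strengths by the inverse relation.

Initial conditions: V ~ Normal(E_L, 5 mV) per neuron, integrated gates
at their steady state for that V, synaptic gates at zero.  The settling
period (10–40 s; defaults 20 s for sweeps, 40 s for single population
runs) absorbs the residual dependence.  At strong electrical coupling
the network is bistable (silent vs tonic); this initialization settles
on the branch reachable from near-rest conditions.

## Numerical integration

Fixed-step second-order Runge–Kutta (midpoint), dt = 0.05 ms by
default; convergence is verified by step-halving (<1% frequency shift)
in the test suite.  Two numerical guards:

- Gate time constants are floored at dt.  Far from the half-voltage the
  cosh-reciprocal profile collapses below the step (τ_mK < 10 µs at
  V ≈ −115 mV, a voltage reachable in the E_L tails), where the gate is
  effectively instantaneous at its steady state but an explicit update
  is unstable.  The floor leaves all physiological trajectories
  untouched and prevents spurious blow-up of deeply hyperpolarized
  neurons.
- Gating variables are clamped to [0, 1] after each full step to absorb
  floating-point overshoot.

Spikes are recorded online as upward crossings of −20 mV with a 2 ms
refractory guard; an offline detector applying the identical rule to
recorded traces is cross-checked against it.  Divergence (|V| beyond
±500 mV) aborts with a diagnostic naming the neuron and time.

## Measurement layer

**Single-neuron bursts.**  Spikes are clustered at an inter-spike gap
threshold of max(300 ms, 3 × median ISI); the median term folds slow
regular spiking into a single cluster so it classifies as tonic.  Two
merge passes follow.  (1) Adjacent clusters merge when their quiescent
gap is below 35% of the mean onset-to-onset interval — conditional
bursters can emit a cycle as a doublet of clusters whose pause is short
on the slow I_NaP-recovery scale (the isolated E_L = −69 mV burster
does exactly this: a precursor clusterlet 0.8 s before the main burst
of each 5.3 s cycle), and a doublet is one burst of the underlying
rhythm.  The mean, not the median, sets the scale because with strict
doublets half the onset intervals are the pause itself; if every gap
qualifies (a uniform high-duty-cycle rhythm) nothing is merged.
(2) When the voltage trace is available, clusters separated by a pause
during which V never falls below −55 mV merge as well: a driven burst
can contain a near-depolarization-block plateau, which is a
within-burst feature, not an interburst interval.  Burst onset is the
first spike of a cluster; the period is the onset-to-onset difference,
the frequency its reciprocal, both undefined below two bursts (the
"N/A" of silent and tonic entries).

**Regimes.**  A neuron is silent with no spikes, bursting with ≥ 2
clusters, tonic otherwise.  The "resting potential" reported for table
comparisons is the mean V over the last 5 s (silent) or the mean V over
quiescent intervals between bursts/spikes (bursting/tonic), excluding
a few ms around each spike.  Averaging the quiescent stretches rather
than taking their minima matches the published values to ≤ 1.1 mV;
the interburst potential of a burster drifts upward as inactivation
recovers, so its minimum systematically undershoots.

**Population activity.**  The population rate is the spike histogram in
100 ms bins divided by N and the bin width — spikes per neuron per
second.  Populational bursts are detected in two passes: provisional
peaks (local maxima above half the trace maximum, ≥ 0.5 s apart) set
the mean burst amplitude; onsets are upward crossings of 30% of that
amplitude; per-burst amplitude is the rate maximum between onsets.  An
explicit threshold can override pass 1 — the deterministic replacement
for manual thresholding of less stable simulations.  Each simulation is
classified into exactly one of four states: *none* (mean rate ≈ 0),
*tonic* (sustained rate ≥ 10 spikes/neuron/s with no down-crossing of
the burst threshold), *low/unstable* (mean burst amplitude < 10
spikes/neuron/s, period coefficient of variation ≥ 50%, or fewer than
three bursts), else *stable bursting*.

**Burst ratio.**  The M:N ratio of two trains is the reduced ratio of
complete cycles inside their common window (using cycle counts rather
than onset counts avoids fencepost bias), with a denominator limit of 6.

**Synchrony index.**  Mean pairwise Pearson correlation of 100-ms
binned spike counts, excluding neurons with constant counts.  The index
increases monotonically across g_Gap ∈ {0, 0.033, 0.066} nS in the
default population.

## Sweep drivers and problem sizes

- `sweep_gw`: one population is sampled per sweep with unit per-edge
  strengths; every (G, W) cell rescales the same matrices, so cells
  differ only in connection strength.  Default protocol per cell: 20 s
  settling + 60 s analysis (a 0.2–0.5 Hz rhythm completes 12–30 cycles).
- `sweep_gnap`: electrical coupling fixed at g_Gap = 0.06 nS; each
  (ḡ_NaP, N_NaP) cell resamples under the same seed so cells differ
  only through the swept parameters.  N_NaP defaults to {20, 30, 40}.
- `carbenoxolone_compare`: the gap-junction-block analogue scales every
  gap conductance by (1 − reduction), default 50%, for each of 5
  parameter randomizations; amplitudes are normalized to the same
  run's baseline.  The default baseline g_Gap = 0.066 nS is the value
  at which the default population reliably reaches stable bursting.
- Two-cell protocol: 20 s settling + 100 s analysis (150 s for rhythms
  near 0.1–0.2 Hz), dt = 0.05 ms.

These window lengths follow the published analysis convention of
omitting 10–20 transitional cycles and averaging the following 10–20.

## What the synthetic population emulates — and what it does not

The generator reproduces the *statistical* description of the modelled
circuit: subpopulation sizes, normal parameter dispersion, Bernoulli
connectivity at the stated probabilities.  It does not model spatial
structure (probabilities measured between *neighbouring* neurons are
applied globally), inhibition, synaptic failure, or any ionic current
beyond Na/K/NaP/leak.  Passing population tests therefore demonstrate
the synchronization and frequency-control mechanisms of this idealized
circuit, not quantitative properties of real spinal networks.

## Known limitations

- The two-cell `t_hmax` is taken from the population default (9 s);
  absolute burst frequencies shift by roughly ±15% over the plausible
  7–10 s range, which is why table comparisons carry a 20% tolerance.
- The synaptic-gate equation admits two parenthesizations; the one
  implemented (rise and decay both scaled by τ_s) is the one consistent
  with the published two-cell voltage shifts and population regime
  structure.  An overall scale uncertainty in synaptic efficacy of
  order tens of percent remains, tied to the spike width above the
  gate's half-activation voltage.
- The population-level stable-bursting windows along G and W reproduce
  the published *sequence* of states (quiescent/unstable → stable
  bursting → tonic) but sit at roughly half the published aggregate
  coupling values; per-edge two-cell behaviour at identical strengths
  matches the published tables, so the discrepancy is specific to the
  population aggregation and is documented rather than calibrated away.
- At strong electrical coupling the model is bistable; outcomes there
  depend on the (unpublished) initial-condition distribution.
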