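# Regime map over aggregate electrical (G, nS) and chemical (W) coupling
# for the default heterogeneous population (100 neurons, 40 with I_NaP).
kind: sweep-gw
seed: 1
out_dir: results/sweep_gw
g_values: [0.0, 1.0, 2.0, 3.0, 4.0]
w_values: [0.0, 2.0, 4.0, 6.0, 8.0]
sim:
  duration: 80.0   # s total; first `settle` seconds excluded from analysis
  settle: 20.0
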