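# pfcpersist

Biophysical modelling of **persistent activity** in prefrontal layer-V
pyramidal neurons, for computational neuroscientists studying the cellular
basis of working memory.

Cortical pyramidal neurons can keep firing for seconds after a stimulus
ends.  This package implements a multi-conductance compartmental model of a
layer-V PFC pyramidal cell in which that persistent firing is carried by a
calcium-activated nonselective cation (CAN) current: a spike burst raises
submembrane calcium, the CAN gate `m` activates by

    alpha = beta * (Ca/Ca_c)^2,   m_inf = alpha / (alpha + beta),
    tau_m = 1 / (alpha + beta)        (beta = 1e-5/ms, Ca_c = 0.4 uM)

and the resulting slow delayed afterdepolarization (dADP, 2-8 mV, ~3 s
decay) can close a regenerative firing loop.  Two phenotypes are built
from one parameter set: regular spiking (RS), and intrinsic bursting (IB)
obtained by doubling the R-type calcium and persistent Na conductances.
The experiment battery asks which stimuli ignite persistence (200 excitatory
synapses on 10 random basal branches, 10 events at 20 Hz, with somatic
inhibition) and which features of the early response — first-AP latency,
leading inter-spike intervals — let a downstream decoder predict it.

Modules: `morphology` (SWC I/O, surrogate cell generator, path distances),
`channels` (gating, CAN, calcium pools, synapses), `simulator`
(Crank-Nicolson cable solver and protocols), `persistence` (trials, sweeps,
spatial analysis), `decode` (LDA ensemble, perceptron, synthetic feature
fixtures), plus a `pfcpersist` CLI.  See `docs/methods.md` for the model
description and design rationale.

## Worked example

```python
from pfcpersist import simulator as sim
from pfcpersist import persistence as per
from pfcpersist.config import load_calibrated

g = load_calibrated()["can"]["g_can_default"]      # dADP ~ 4 mV point
cell = sim.build_cell("RS", nmda_ratio=1.2, g_can=g, noise=True)

print(round(sim.measure_input_resistance(cell), 1), "MOhm")
d = sim.dadp_protocol(cell, n_pulses=5)
print(round(d.measurement.amplitude, 2), "mV dADP,",
      round(d.measurement.tau_decay), "ms decay")

trial = per.run_trial(cell, per.TrialConfig(trial_seed=3))
print(trial.persistent, round(trial.ap_latency, 2), "ms latency,",
      trial.n_stim_spikes, "stimulus spikes")
```

prints

```
80.6 MOhm
4.0 mV dADP, 3246 ms decay
True 2.02 ms latency, 37 stimulus spikes
```

i.e. the calibrated cell has the physiological 81 MOhm input resistance, a
5-spike burst evokes a dADP in the experimental 2-8 mV band decaying with
the ~3 s time constant, and at this CAN conductance a randomized
basal-stimulation trial ignites persistent activity (firing that outlives
the stimulus by more than 3 s).

Command-line equivalents:

```bash
pfcpersist validate --phenotype RS
pfcpersist sweep --phenotype RS --n-trials 10 --seed 1
pfcpersist trials --phenotype RS --g-can 5.2e-4 --n-trials 20
pfcpersist decode --classifier lda --trials-csv results/trials_RS_N1.2.csv
```

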