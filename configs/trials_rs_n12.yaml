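# randomized basal-stimulation trial corpus at a fixed CAN conductance
experiment: trials
phenotype: RS
nmda_ratio: 1.2
g_can: 5.2e-4
n_trials: 50
base_seed: 1
noise: true
out_dir: results
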