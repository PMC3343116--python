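# 50%-persistence dADP threshold, RS phenotype, control NMDA ratio
experiment: sweep
phenotype: RS
nmda_ratio: 1.2
n_trials: 10
base_seed: 1
noise: true
out_dir: results
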