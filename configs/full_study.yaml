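# Full simulation study: six distributions, the complete sample-size grid
# n = 50(50)200, 250(250)1000, all seven LoA estimators, 5000 replicates
# per cell.  Run with:
#   nploa run-study --config configs/full_study.yaml --out study_out
distributions: [normal, lognormal, beta_2_5, beta_2_2, chisq_4, exp_1]
sample_sizes: [50, 100, 150, 200, 250, 500, 750, 1000]
# "no" must stay quoted: bare no is YAML 1.1 for boolean false
estimators: [ba, sq, hd, bp, hdlc, sv, "no"]
replicates: 5000
seed: 20201111
lognormal_meanlog: 0.0
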