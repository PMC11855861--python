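# Default synthetic-cohort configuration (all values shown are the built-in
# defaults of demandtx.SimulationConfig; edit and pass via --config).

# cohort design
n_meth: 6
n_sal: 6
ladder: [1, 3, 5, 8, 12, 18, 26, 38, 58, 86, 130, 195, 292]

# demand-curve truth: shared range constant and per-group lognormal
# hyperparameters for Q0 (mg/kg at zero price) and alpha; the values match
# the bundled reference cohort's per-group geometric means at k = 2.4
k_true: 2.4
q0_logmean_meth: 1.93
q0_logsd_meth: 0.64
q0_logmean_sal: 0.10
q0_logsd_sal: 0.56
alpha_logmean_meth: -6.35
alpha_logsd_meth: 0.66
alpha_logmean_sal: -3.78
alpha_logsd_sal: 0.39

# consumption realization: log10-additive Gaussian noise; unit dose mg/kg
# per infusion (ladder truncation fires when realized infusions round to 0)
noise_sd_log10: 0.1
unit_dose: 0.05

# expression matrix: NB counts, log-mean linear in EV for the linked genes
n_genes: 2000
frac_linked: 0.025
slope_linked: 0.5
baseline_logmean: 3.0
baseline_logsd: 1.5
theta: 10.0
libsize_jitter: 0.1
drop_meth_pfc_sample: false
region: PFC

seed: 0
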