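# Default configuration for the fate-switch pipeline.
# Calibrated so that, with signaling saturated (s=1) and the preferred
# inhibits_nanog coupling, the autonomous circuit is a symmetric bistable
# toggle (three equilibria, two stable), a 6 h pulse of heterogeneous
# exogenous GATA splits a population bimodally by 30 h, and lowering s
# raises the critical dose.
model:
  alpha_N: 5.0        # max NANOG production [conc/h]
  alpha_G: 1.0        # max endogenous GATA production [conc/h]
  K_GN: 0.3           # total-GATA repression threshold on NANOG [conc]
  K_NG: 0.3           # NANOG repression threshold on GATA [conc]
  h_N: 4.0            # Hill exponent, GATA -| NANOG
  h_G: 4.0            # Hill exponent, NANOG -| GATA
  gamma_N: 0.5        # NANOG degradation [1/h]
  gamma_G: 0.5        # endogenous GATA degradation [1/h]
  gamma_X: 0.5        # exogenous GATA degradation [1/h]
  s: 1.0              # FGF/MAPK signaling level (0 = inhibited, 1 = saturated)
  K_s: 0.5            # signaling half-effect constant
  m: 2.0              # signaling Hill exponent
  mode: inhibits_nanog  # none | promotes_gata | inhibits_nanog
protocol:
  t_start: 0.0        # pulse onset [h]
  t_end: 6.0          # pulse offset [h]
  t_final: 30.0       # end of chase [h]
population:
  dose_family: lognormal
  dose_location: -1.05   # mean of log D; ~= log critical dose at s=1
  dose_scale: 0.8        # sd of log D (long-tailed induced expression)
  n: 2000
  seed: 0
noise:
  sigma_mult: 0.2     # log-normal multiplicative measurement sd
  background: 0.5     # additive background mean [a.u.] (5% of alpha_N/gamma_N)
  background_sd: 0.05 # additive background sd [a.u.]
  label_flip: 0.0     # probability an end-point fate label is wrong
analysis:
  n_boot: 1000        # bootstrap replicates for ROC uncertainties
  frame_interval: 0.25   # time-lapse cadence [h]
  cluster_k: 2
  kde_bandwidth: silverman
  peak_prominence_frac: 0.05
  s_levels: [1.0, 0.5, 0.25]
version: "0.1.0"
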