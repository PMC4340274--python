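# Yeast Grx1 HED-assay profile: fitted rate constants and background
# species concentrations (uM, s).
k1: 0.073
k2_wt: 4.23e-6
k2p_mut: 4.2e-3
k_hed: 0.073
keq_deglut: 1.0
gr_kcat: 900.0
gr_K_NADPH: 15.0
gr_K_GSSG: 74.6
gr_conc: 0.02
grx_tot: 0.24
species:
  NADPH: 250.0
  NADP: 1.0
  GSH: 998.0
  GSSG: 1.0
  HED: 70.0
  GrxSH2: 0.12
  GrxSS: 0.12
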