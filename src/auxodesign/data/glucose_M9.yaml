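# Glucose M9 minimal medium for iJO1366-style E. coli models, as max-uptake
# allowances (mmol/gDW/hr) on BiGG exchange ids. Values mirror the model's
# default minimal medium with maximum oxygen uptake capped at 20.
EX_ca2_e: 1000
EX_cbl1_e: 0.01
EX_cl_e: 1000
EX_co2_e: 1000
EX_cobalt2_e: 1000
EX_cu2_e: 1000
EX_fe2_e: 1000
EX_fe3_e: 1000
EX_glc__D_e: 10
EX_h2o_e: 1000
EX_h_e: 1000
EX_k_e: 1000
EX_mg2_e: 1000
EX_mn2_e: 1000
EX_mobd_e: 1000
EX_na1_e: 1000
EX_nh4_e: 1000
EX_ni2_e: 1000
EX_o2_e: 20
EX_pi_e: 1000
EX_sel_e: 1000
EX_slnt_e: 1000
EX_so4_e: 1000
EX_tungs_e: 1000
EX_zn2_e: 1000
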