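# Tirzepatide physicochemical and ADME parameters (FDA label / DrugBank /
# PubChem values plus the optimized absorption and clearance constants).
molecular_weight: 4813.5        # g/mol
log_p: -6.8                     # octanol/water
solubility_mg_ml: 1.0           # upper bound ("<1 mg/mL"); informational
fu: 0.01                        # unbound fraction in plasma
ka: 0.0996                      # 1/h, first-order SC absorption
bioavailability: 0.81           # SC
cl_spec_peptidase: 0.35         # L/umol/min, specific peptidase clearance
peptidase_conc: 1.0             # umol/L, ubiquitous tissue concentration
gfr_fraction: 1.0               # freely filtered, no secretion/reabsorption
f_urine: 0.66                   # fraction of elimination appearing in urine
renal_cl_param: 0.12            # 1/min, reported optimized value (ambiguous
                                # normalization; engine derives operative renal
                                # clearance from the f_urine constraint)
partition_method: pksim_standard_approx
fixed_kp: 1.0
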