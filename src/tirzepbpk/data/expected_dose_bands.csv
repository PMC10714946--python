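# Dose adjustments for pediatric tirzepatide by age band and weight class,
# as reported in the published pediatric PBPK dose-matching analysis.
# no_adjustment = full adult reference dose (5 mg) retained.
age_band,weight_class,dose_band_mg
children_10_12,normal,2.5-3.125
children_10_12,obese,3.125-3.75
early_adol_12_15,normal,3.125-3.75
early_adol_12_15,obese,3.75-5
adol_15_18,normal,3.75-5
adol_15_18,obese,no_adjustment
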