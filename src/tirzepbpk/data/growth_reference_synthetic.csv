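# Synthetic growth reference (CDC/ICRP-style): median height/weight by age and
# sex for ages 10-18, plus BMI-for-age 95th-percentile curves in LMS form
# (P95 = M*(1+L*S*1.645)^(1/L)). These are hand-constructed smooth curves that
# track published growth-chart medians to within a few percent; they are
# shipped so the package needs no download, and are NOT a published dataset.
sex,age_years,height_cm,weight_kg,bmi_l,bmi_m,bmi_s
male,10,138.4,31.9,-2.0,16.65,0.13
male,11,143.5,35.8,-2.0,17.38,0.13
male,12,149.1,40.5,-2.0,18.22,0.13
male,13,156.0,45.8,-2.0,18.82,0.13
male,14,163.2,51.4,-2.0,19.30,0.13
male,15,169.0,56.5,-2.0,19.78,0.13
male,16,172.9,60.8,-2.0,20.34,0.13
male,17,175.2,64.4,-2.0,20.98,0.13
male,18,176.1,66.9,-2.0,21.57,0.13
female,10,138.6,32.9,-2.0,17.13,0.13
female,11,144.7,37.2,-2.0,17.77,0.13
female,12,151.2,41.8,-2.0,18.28,0.13
female,13,155.9,45.8,-2.0,18.84,0.13
female,14,158.7,49.1,-2.0,19.50,0.13
female,15,160.8,51.9,-2.0,20.07,0.13
female,16,162.0,53.4,-2.0,20.35,0.13
female,17,162.8,54.8,-2.0,20.68,0.13
female,18,163.3,56.7,-2.0,21.26,0.13
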