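# Predicted vs observed adult PK parameters, single SC doses of tirzepatide,
# compiled from published adult clinical PK comparisons (five studies, 2.5-8 mg).
# auc_window: 0_inf except where the source comparison used 0-168 h (flagged 0_168).
# fold_error_reported is the value printed in the source comparison (pred/obs
# convention). CL/F for the japanese 5 mg study is NA in the source despite a
# printed fold error of 1.54; it is excluded from AFE computations.
study_id,dose_mg,parameter,auc_window,predicted,observed,fold_error_reported
asian,2.5,auc,0_inf,56546,53200,1.06
asian,2.5,cmax,,228.1,231.0,0.99
asian,2.5,t_half,,128.3,120.0,1.07
asian,2.5,tmax,,54.7,24.0,2.28
asian,2.5,cl_over_f,,0.0440,0.0470,0.94
asian,5,auc,0_inf,113085,90500,1.25
asian,5,cmax,,494.2,397.0,1.24
asian,5,t_half,,128.0,123.0,1.04
asian,5,tmax,,40.0,24.1,1.66
asian,5,cl_over_f,,0.0442,0.0553,0.80
asian,8,auc,0_inf,223391,169000,1.32
asian,8,cmax,,901.4,874.0,1.03
asian,8,t_half,,128.3,111.0,1.16
asian,8,tmax,,54.7,48.0,1.14
asian,8,cl_over_f,,0.0358,0.0472,0.76
japanese,5,auc,0_168,113085,104000,1.09
japanese,5,cmax,,494.2,364.0,1.36
japanese,5,t_half,,128.0,127.0,1.01
japanese,5,tmax,,40.0,48.0,0.83
japanese,5,cl_over_f,,NA,NA,1.54
european_a,5,auc,0_inf,113084,80500,1.40
european_a,5,cmax,,494.2,339.0,1.46
european_a,5,t_half,,128.0,121.0,1.06
european_a,5,tmax,,40.0,48.0,0.83
european_a,5,cl_over_f,,0.0442,0.0621,0.71
european_b,5,auc,0_inf,113084,84300,1.34
european_b,5,cmax,,494.2,510.0,0.97
european_b,5,t_half,,128.0,124.0,1.03
european_b,5,tmax,,40.0,24.0,1.67
european_b,5,cl_over_f,,0.0442,0.0593,0.75
chinese,2.5,auc,0_168,30673,35100,0.87
chinese,2.5,cmax,,228.8,306.0,0.75
chinese,2.5,t_half,,128.3,139.0,0.92
chinese,2.5,tmax,,54.7,24.0,2.28
chinese,2.5,cl_over_f,,0.0441,0.0384,1.15
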