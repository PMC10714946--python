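# Predicted vs observed adult PK parameters, once-weekly multiple SC dosing,
# compiled from published adult clinical PK comparisons. regimen encodes the
# escalation as "dose_mg:weeks" stages separated by "+", 168 h apart.
# AUC is over the final weekly interval. The asian 4.5 mg predicted AUC is
# stored as 98878 (the source prints 988780, inconsistent with its own fold
# error 0.96 = 98878/103000). For the japanese 5 mg row the source printed
# inverse-convention fold errors (obs/pred); fold_error_reported keeps the
# printed values, so for that row they do NOT equal predicted/observed.
study_id,target_dose_mg,regimen,parameter,predicted,observed,fold_error_reported
asian,4.5,4.5:4,auc_0_168,98878,103000,0.96
asian,4.5,4.5:4,cmax,717.5,884.0,0.81
asian,4.5,4.5:4,t_half,128.3,132.0,0.97
asian,4.5,4.5:4,tmax,42.0,24.2,1.74
asian,10,5:2+8:1+10:1,auc_0_168,189535,198000,0.96
asian,10,5:2+8:1+10:1,cmax,1378.0,1510.0,0.91
asian,10,5:2+8:1+10:1,t_half,128.3,126.0,1.02
asian,10,5:2+8:1+10:1,tmax,45.3,24.2,1.87
japanese,5,5:8,auc_0_168,112988,104000,0.92
japanese,5,5:8,cmax,819.8,838.0,1.02
japanese,5,5:8,t_half,128.3,127.0,0.99
japanese,5,5:8,tmax,41.2,48.0,1.17
japanese,10,2.5:2+5:2+10:4,auc_0_168,222479,192000,1.16
japanese,10,2.5:2+5:2+10:4,cmax,1614.2,1520.0,1.06
japanese,10,2.5:2+5:2+10:4,t_half,128.3,135.0,0.95
japanese,10,2.5:2+5:2+10:4,tmax,41.0,24.0,1.71
japanese,15,5:2+10:4+15:2,auc_0_168,318900,285000,1.12
japanese,15,5:2+10:4+15:2,cmax,2314.5,2270.0,1.02
japanese,15,5:2+10:4+15:2,t_half,128.3,121.0,1.06
japanese,15,5:2+10:4+15:2,tmax,42.7,48.0,0.89
chinese,5,2.5:4+5:4,auc_0_168,108794,110000,0.99
chinese,5,2.5:4+5:4,cmax,789.5,915.0,0.86
chinese,5,2.5:4+5:4,t_half,130.6,124.0,1.05
chinese,5,2.5:4+5:4,tmax,42.0,24.0,1.75
chinese,10,2.5:4+5:4+7.5:4+10:4,auc_0_168,221867,263000,0.84
chinese,10,2.5:4+5:4+7.5:4+10:4,cmax,1609.9,2200.0,0.73
chinese,10,2.5:4+5:4+7.5:4+10:4,t_half,128.4,132.0,0.97
chinese,10,2.5:4+5:4+7.5:4+10:4,tmax,41.8,24.0,1.74
chinese,15,2.5:4+5:4+7.5:4+10:4+12.5:4+15:4,auc_0_168,336231.5,357000,0.94
chinese,15,2.5:4+5:4+7.5:4+10:4+12.5:4+15:4,cmax,2439.7,2930,0.83
chinese,15,2.5:4+5:4+7.5:4+10:4+12.5:4+15:4,t_half,128.25,126,1.02
chinese,15,2.5:4+5:4+7.5:4+10:4+12.5:4+15:4,tmax,41.5,24,1.73
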