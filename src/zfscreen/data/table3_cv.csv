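# Cardiotoxicity assay repeatability: inter-assay coefficient of variation
# (CV = SD x 100 / mean) of heart rate over ten independent experiments per
# compound/concentration condition (20 embryos per condition and plate).
predominant_effect,compound,concentration_um,interassay_cv_pct
No effect,Lidocaine,5,3.2
Bradycardia,Lidocaine,50,2.5
Bradycardia,Thioridazine,5,3.7
Arrhythmia,Thioridazine,50,7.3
Arrhythmia,Haloperidol,5,5.4
Cardiac arrest,Haloperidol,50,9.3
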