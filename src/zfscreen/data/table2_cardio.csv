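# Cardiotoxicity validation panel: 35 reference compounds with known human
# cardiac effects, blind-screened on 48 hpf Cmlc2:GFP embryos at 1-200 uM.
# The source table title says "34 small bioactive compounds" but the body
# lists 35 rows; all 35 are transcribed here.
# human_effect: known predominant cardiac effect in humans.
# observed_effect: predominant automated zebrafish classification.
# verdict: TP/TN/FN/FP as printed in the source table.
compound,family,human_effect,observed_effect,verdict
Lidocaine,Antiarrhythmic,Bradycardia,Bradycardia,TP
Flecainide,Antiarrhythmic,QT-prolong.,Arrhythmia 2:1,TP
Propafenone,Antiarrhythmic,QT-prolong.,Arrhythmia 2:1,TP
Amiodarone,Antiarrhythmic,QT-prolong.,Arrhythmia 2:1,TP
Propranolol,Beta-Blocker,Bradycardia,Bradycardia,TP
Timolol,Beta-Blocker,Bradycardia,Bradycardia,TP
Thioridazine,Antipsychotic,QT-prolong.,Arrhythmia 2:1,TP
Haloperidol,Antipsychotic,QT-prolong.,Arrhythmia 2:1,TP
Ziprasidone,Antipsychotic,QT-prolong.,Bradycardia,FN
Pimozide,Antipsychotic,QT-prolong.,Arrhythmia 2:1,TP
Sertindol,Antipsychotic,QT-prolong.,Arrhythmia 2:1,TP
Risperidone,Antipsychotic,QT-prolong.,Arrhythmia 2:1,TP
Fluoxetine,Antidepressant,Arrhythmia,Arrhythmia,TP
Doxorrubicin,Antitumoral,No effect,No effect,TN
Tamoxifen,Antitumoral,Arrhythmia,Arrhythmia,TP
Lapatinib,Antitumoral,No effect,No effect,TN
Verapamil,Calcium blocker,Bradycardia,Bradycardia,TP
Diltiazem,Calcium blocker,Bradycardia,Bradycardia,TP
Nitrendipine,Calcium blocker,Cardiac arrest,Cardiac arrest,TP
Terodiline,Calcium blocker,QT-prolong.,Arrhythmia 2:1,TP
Pilocarpine,Colinergic agonist,No effect,No effect,TN
Nicotine,Colinergic agonist,Bradycardia,Bradycardia,TP
Astemizol,Antihistamine,QT-prolong.,Arrhythmia 2:1,TP
Terfenadine,Antihistamine,QT-prolong.,Arrhythmia 2:1,TP
Fexofenadine,Antihistamine,No effect,No effect,TN
Halofantrine,Antiinfective,QT-prolong.,Arrhythmia 2:1,TP
Foscarnet,Antiinfective,Bradycardia,Bradycardia,TP
Cisapride,Gastrointestinal agent,QT-prolong.,Arrhythmia 2:1,TP
Estradiol,Hormones,Bradycardia,Bradycardia,TP
Testosterone,Hormones,Bradycardia,Bradycardia,TP
L-768763,Iks blocker,QT-prolong.,Bradycardia,FN
Chromanol 293b,Iks blocker,QT-prolong.,No effect,FN
SDZ-201106,Ina opener,QT-prolong.,Arrhythmia 2:1,TP
Digitoxin,Other,Bradycardia,Cardiac arrest,TP
Ketanserin,Other,Bradycardia,Bradycardia,TP
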