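# Angiogenesis validation panel: 18 known angiogenesis inhibitors (tyrosine
# kinase inhibitors and other anti-angiogenic agents) and 10 compounds with
# no anti-angiogenic action in prior HUVEC/xenopus screens.
# ic50_tv_um / ic50_cv_um: IC50 against total / complete vessel number, uM,
# when a clear dose-dependent effect allowed fitting; otherwise the minimum
# effective concentration is given. The "?" for Paclitaxel is transcribed
# verbatim (effect obtained only by yolk injection, no concentration scale).
compound,human_effect,observed_effect,verdict,ic50_tv_um,ic50_cv_um,effective_concentration_um
KRN633,Inhibitor,Inhibited,TP,0.035,0.026,
ZD6474 (Vandetanib),Inhibitor,Inhibited,TP,,,100
Sunitinib malate,Inhibitor,Inhibited,TP,2.6,1.7,
Sorafenib Tosylate,Inhibitor,Inhibited,TP,0.78,0.53,
PD173074,Inhibitor,Inhibited,TP,,,100
PD166866,Inhibitor,Inhibited,TP,43.9,16,
AG-1296,Inhibitor,Inhibited,TP,,,20
PDGFR tyr kin inhibitor V,Inhibitor,Inhibited,TP,0.19,0.14,
Tie2 Kinase inhibitor,Inhibitor,No effect,FN,,,
Bosutinib,Inhibitor,Inhibited,TP,,,50
AG1478,Inhibitor,Inhibited,TP,22.8,13,
Indirubin-3'-oxime,Inhibitor,Inhibited,TP,18.3,4.2,
Fumagillin,Inhibitor,No effect,FN,,,
NS-398,Inhibitor,Inhibited,TP,,,30
HIF-1 Inhibitor,Inhibitor,No effect,FN,,,
NVP-BEZ235,Inhibitor,Inhibited,TP,,,10
2-Methoxyestradiol,Inhibitor,Inhibited,TP,30.6,10.2,
Paclitaxel,Inhibitor,Inhibited,TP,,,?
Tyrphostin AG490,No effect,No effect,TN,,,
Bestatin,No effect,No effect,TN,,,
Acetamide,No effect,No effect,TN,,,
E64,No effect,No effect,TN,,,
O6-benzylguanine,No effect,No effect,TN,,,
Cyclosporine A,No effect,No effect,TN,,,
4-Methylpyrazole hydrochloride,No effect,No effect,TN,,,
N-Acetyl-L-cysteine,No effect,No effect,TN,,,
Amiodarone hydrochloride,No effect,No effect,TN,,,
cis-Diammineplatinum(II) dichloride,No effect,No effect,TN,,,
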