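name,dock_score,pEC50_mlr,pEC50_svm,pEC50_bnt,cyp2d6_probability,hepatotoxicity_probability,ppb_level
5-hydroxy-L-tryptophan,148.721,5.89,6.62,6.59,0.069,0.291,0
abrine,142.592,6.31,6.63,6.44,0.049,0.642,0
saussureamine C,135.304,5.90,7.27,7.91,0.415,0.450,0
saussureamine B,124.688,8.85,7.63,8.00,0.356,0.708,0
saussureamine A,103.030,7.59,7.81,7.64,0.336,0.754,0
T2384,77.618,7.52,7.06,8.50,0.069,0.953,2
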