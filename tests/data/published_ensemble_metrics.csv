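ensemble_id,TPR,TNR,PPV,ACC,ERR,BAC,GM,YI,DP,F1,MCC,KAPPA
Multi-5,0.496933,0.996798,0.464183,0.994023,0.005977,0.746865,0.703805,0.493730,1.372298,0.480000,0.477278,0.476998
Multi-4,0.473620,0.997740,0.539106,0.994830,0.005170,0.735680,0.687422,0.471359,1.433602,0.504246,0.502721,0.501658
Multi-3,0.365644,0.999116,0.697892,0.995600,0.004400,0.682380,0.604418,0.364761,1.552263,0.479871,0.503265,0.477878
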