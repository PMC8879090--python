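ensemble_id,members,threshold,tp,tn,fp,fn
Multi-5,Inc_Res_v2;Pns_lrg;Inc_v4;Ns_lrg;Inc_v3,3,810,291039,935,820
Multi-4,Inc_Res_v2;Pns_lrg;Inc_v4;Ns_lrg,3,772,291314,660,858
Multi-3,Inc_Res_v2;Pns_lrg;Inc_v4,3,596,291716,258,1034
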