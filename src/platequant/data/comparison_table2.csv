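sample_id,matrix,candidate_mean,candidate_sd,reference_mean,reference_sd,label
Ctr,serum,4.9,0.1,4.9,0.5,5
Ord,serum,10.6,0.3,10.2,0.5,10
Bet,serum,9.7,0.6,10.2,0.4,10
Rvl,serum,15.0,0.1,15.6,0.6,15
Skn,serum,4.8,0.2,5.20,0.02,
Oly,serum,6.09,0.06,1.56,0.01,
Rvu,serum,3.81,0.09,3.4,0.1,
Num,cream,3.4,0.1,3.0,0.1,3
Msn,cream,4.57,0.02,4.31,0.06,4
Stm,cream,5.3,0.2,5.68,0.08,5
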