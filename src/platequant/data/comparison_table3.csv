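sample_id,matrix,candidate_mean,candidate_sd,reference_mean,reference_sd,label
Ctr,serum,4.8,0.2,4.9,0.5,5
Ord,serum,10.6,0.4,10.2,0.5,10
Oly,serum,1.58,0.03,1.4,0.1,
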