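ligand_volume_ml,metal_volume_ml
1,9
2,8
3,7
4,6
5,5
6,4
7,3
8,2
9,1
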