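library	category	n_targets
CL	0	10
CL	1	26
CL	2	522
CL	3	23
CL	4	818
DL	0	26
DL	1	9
DL	2	708
DL	3	73
DL	4	507
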