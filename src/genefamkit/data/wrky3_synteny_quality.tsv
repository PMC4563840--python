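species_pair	clade	quality_pct
At-Os	1	24.56
At-Ptr	2	15.38
At-Ptr	3	24.01
At-Ptr	4	38.10
At-Vv	2	26.21
At-Vv	3	26.99
At-Vv	4	38.10
Os-Ptr	4	14.29
Os-Vv	4	17.78
Ptr-Vv	1	44.63
Ptr-Vv	2	45.53
Ptr-Vv	3	36.39
Ptr-Vv	4	42.19
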