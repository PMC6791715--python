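sample_id	time_h	replicate	mapped_reads	rrna_reads
WT_0_1	0	1	61906718	60713758
WT_0_2	0	2	61117544	59826984
WT_6_1	6	1	54468281	53756387
WT_6_2	6	2	52436258	51759879
WT_12_1	12	1	54054132	53271826
WT_12_2	12	2	57646891	56798096
WT_24_1	24	1	33003343	32498394
WT_24_2	24	2	53962216	53018166
WT_48_1	48	1	62796702	61500435
WT_48_2	48	2	34693098	34020090
WT_72_1	72	1	63625946	62530758
WT_72_2	72	2	51866662	50779793
WT_96_1	96	1	63255801	62039033
WT_96_2	96	2	61187496	60080963
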