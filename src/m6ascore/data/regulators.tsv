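gene	role	weight_sign
METTL3	writer	1
METTL14	writer	1
METTL16	writer	1
WTAP	writer	1
VIRMA	writer	1
ZC3H13	writer	-1
RBM15	writer	1
RBM15B	writer	1
CBLL1	writer	1
FTO	eraser	-1
ALKBH5	eraser	-1
YTHDC1	reader	1
YTHDC2	reader	1
YTHDF1	reader	1
YTHDF2	reader	1
YTHDF3	reader	1
HNRNPA2B1	reader	1
HNRNPC	reader	1
FMR1	reader	1
LRPPRC	reader	1
ELAVL1	reader	1
IGF2BP1	reader	1
IGF2BP2	reader	-1
IGF2BP3	reader	1
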