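species	formula	adduct	class	diagnostic_mzs	diagnostic_labels
PC(18:1_18:1)	C44H84NO8P	+Na	PC	749.5092;625.5166;467.2533	-N(CH3)3;-phosphocholine;-N(CH3)3-FA(18:1)
PC(18:0_18:2)	C44H84NO8P	+Na	PC	749.5092;625.5166;465.2376;469.2689	-N(CH3)3;-phosphocholine;-N(CH3)3-FA(18:0);-N(CH3)3-FA(18:2)
PC(38:5)	C46H82NO8P	+H	PC	184.0733;577.5195;496.3402	phosphocholine+H;frag2;frag3
PC(O-36:3)	C44H84NO7P	+K	PC-O	739.4903;615.4998;441.2501	frag1;frag2;frag3
PC(16:0_18:1)	C42H82NO8P	+Na	PC	723.4935;599.5010;467.2533;441.2376	-N(CH3)3;-phosphocholine;-N(CH3)3-FA(16:0);-N(CH3)3-FA(18:1)
PC(18:0_18:1)	C44H86NO8P	+Na	PC	751.5248;627.5323;467.2533;469.2689	-N(CH3)3;-phosphocholine;-N(CH3)3-FA(18:0);-N(CH3)3-FA(18:1)
PC(16:1_20:0)	C44H86NO8P	+Na	PC	751.5248;627.5323;497.3002;439.2220	-N(CH3)3;-phosphocholine;-N(CH3)3-FA(16:1);-N(CH3)3-FA(20:0)
PC(38:4)	C46H84NO8P	+H	PC	184.0733;586.5402;504.3511	phosphocholine+H;frag2;frag3
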