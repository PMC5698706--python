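# Density-functional reduction-potential shifts (mV) at eps=78.4, with the
# experimental ranges, transcribed for table lookup; no DFT is computed here.
# The M121Q experimental range is printed ambiguously ('-64-91') and is
# excluded from range-aware scoring by default (exp fields left blank).
label	ddE_mV	source	exp_low_mV	exp_high_mV	note
F114N	170	T1	84	145	
N47S	65	T1	90	161	
N47P	-81	T1	-68	-27	
F114P	-80	T1	-111	-56	
M121V	89	T2	125	145	
M121L	129	T2	86	115	
M121G	88	T2	7	7	
M121N	88	T2	28	48	
M121Q	-124	T2			exp range printed '-64-91' (ambiguous sign)
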