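# SYNTHETIC reconstruction of the axial-ligand hydrophobicity calibration set.
# M121G and the M121L/M121V midpoints come from printed experimental values;
# M121A and M121I are reconstructed so that unweighted OLS reproduces the
# published calibration constants a=25.8 mV/KD, b=64.7 mV.
mutant	delta_kd	ddE_mV	low_mV	high_mV
M121G	-2.3	7.0		
M121A	-0.1	61.4		
M121L	1.9	100.5	86	115
M121V	2.3	135.0	125	145
M121I	2.6	133.2		
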