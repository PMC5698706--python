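# SYNTHETIC placeholder copper-site charge set (the NBO-derived charges are
# not published); the redox electron is spread over Cu, S(Cys112) and the
# coordinating His nitrogens so that total(OX) - total(RED) = +1.000 e.
# Copper radius 1.71 A in both oxidation states. Override with --cu-charges.
oxidation_state	role	atom_name	charge	radius
OX	CU	CU	0.8500	1.71
OX	CYS112	SG	-0.6000	
OX	CYS112	CB	0.0500	
OX	HIS46	NE2	-0.5000	
OX	HIS117	NE2	-0.5000	
RED	CU	CU	0.4000	1.71
RED	CYS112	SG	-0.9000	
RED	CYS112	CB	0.0500	
RED	HIS46	NE2	-0.6250	
RED	HIS117	NE2	-0.6250	
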