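protein_id	reference_concentration
A2M	200.0
B2M	0.2
C1R	5.0
C2	2.5
C6	4.5
C9	6.0
CFP	2.0
CP	30.0
F10	1.0
F12	3.0
F2	10.0
F7	0.05
F8	0.015
F9	0.5
HP	100.0
KLKB1	4.0
MB	0.005
MBL2	0.15
SERPINA1	150.0
TFRC	0.2
TTR	25.0
VWF	1.0
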