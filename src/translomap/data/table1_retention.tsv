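marker	Hb1.8	Hb2.5	Hb1.3	Hb1.4	Hb1.5	Hb1.6	Hb1.7	Hb1.9	Hb2.1	Hb2.2	Hb2.3	Hb2.4
S0142	1	1	0	0	0	0	0	0	0	0	0	0
SWR2516	0	0	0	0	0	0	1	0	1	1	0	1
SW492	0	0	1	0	0	1	0	0	0	0	1	0
SW1856	0	0	0	0	1	0	0	1	0	0	1	0
SWC19	0	0	0	0	1	1	0	0	1	0	1	1
SW168	0	0	1	0	0	0	0	0	0	0	0	0
S0084	0	0	0	0	0	0	0	0	0	0	0	0
SW1125	0	0	0	0	0	0	0	0	0	0	0	0
S0004	0	0	1	0	0	1	0	0	0	0	0	0
SW1341	1	0	1	1	1	1	1	0	1	0	1	1
SWR1004	0	0	0	0	0	0	0	0	0	0	0	0
S0062	0	0	0	0	0	0	0	0	0	0	0	0
S0213	1	1	0	1	1	0	1	1	0	1	1	0
Sw2429	1	1	0	1	1	0	1	1	0	1	1	0
SW251	1	1	0	1	1	0	1	1	0	1	1	0
SW2527	1	1	0	1	1	0	1	1	0	1	1	0
SW487	0	1	0	0	0	0	0	0	0	0	0	0
S0174	0	1	0	0	0	0	0	0	0	0	0	0
SW1525	0	1	0	0	0	0	0	0	0	0	0	0
SW860	0	1	0	0	0	0	0	0	0	0	0	0
S0034	0	1	0	0	0	0	0	0	0	0	0	0
S0032	0	1	0	0	0	0	0	0	0	0	0	0
SW1432	0	1	0	0	0	0	0	0	0	0	0	0
SW2597	0	1	0	0	0	0	0	0	0	0	0	0
SW45	1	1	0	1	1	0	1	1	0	1	1	0
S0217	1	1	0	1	1	0	1	1	0	1	1	0
S0073	1	1	0	1	1	0	1	1	0	1	1	0
S0764	1	1	0	1	1	0	1	1	0	1	1	0
SW1996	1	1	0	1	1	0	1	1	0	1	1	0
SW286	1	1	0	1	1	0	1	1	0	1	1	0
Sw270	1	1	0	1	1	0	1	1	0	1	1	0
S0214	1	1	0	1	1	0	1	1	0	1	1	0
SW512	1	1	0	1	1	0	1	1	0	1	1	0
SW524	0	1	0	0	0	0	0	0	0	0	0	0
SW2435	0	1	0	0	0	0	0	0	0	0	0	0
S0067	0	1	0	0	0	0	0	0	0	0	0	0
SW2066	0	1	0	0	0	0	0	0	0	0	0	0
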