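name	chrom	cm	pos_bp	phase
S0142	SSC1	83	NA	MICROSAT
SWR2516	SSC2	1	NA	MICROSAT
SW492	SSC6	69	NA	MICROSAT
SW1856	SSC7	64	NA	MICROSAT
SWC19	SSC10	50	NA	MICROSAT
SW168	SSC12	70	NA	MICROSAT
S0084	SSC13	61	NA	MICROSAT
SW1125	SSC14	22	NA	MICROSAT
S0004	SSC15	16	NA	MICROSAT
SW1341	SSC16	40	NA	MICROSAT
SWR1004	SSC17	15	NA	MICROSAT
S0062	SSC18	43	NA	MICROSAT
S0213	SSC3	7.8	NA	MICROSAT
Sw2429	SSC3	17	NA	MICROSAT
SW251	SSC3	42.3	21948000	MICROSAT
SW2527	SSC3	42.3	NA	MICROSAT
SW487	SSC3	42.8	31261000	MICROSAT
S0174	SSC3	43	NA	MICROSAT
SW1525	SSC3	45	NA	MICROSAT
SW860	SSC3	47	NA	MICROSAT
S0034	SSC3	49.8	NA	MICROSAT
S0032	SSC3	50.6	NA	MICROSAT
SW1432	SSC3	51	NA	MICROSAT
SW2597	SSC3	52	NA	MICROSAT
SW45	SSC4	55.9	NA	MICROSAT
S0217	SSC4	69.6	NA	MICROSAT
S0073	SSC4	74.4	NA	MICROSAT
S0764	SSC4	75	NA	MICROSAT
SW1996	SSC4	77	NA	MICROSAT
SW286	SSC4	78.3	NA	MICROSAT
Sw270	SSC4	79.3	NA	MICROSAT
S0214	SSC4	79.3	NA	MICROSAT
SW512	SSC4	80.5	106511000	MICROSAT
SW524	SSC4	99.3	NA	MICROSAT
SW2435	SSC4	102.8	120509000	MICROSAT
S0067	SSC4	102.8	NA	MICROSAT
SW2066	SSC4	121	NA	MICROSAT
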