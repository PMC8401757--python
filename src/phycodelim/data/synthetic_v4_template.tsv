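# Synthetic demonstration template for the SSU V4 helix annotation.
# Coordinates are 1-based inclusive on an ungapped synthetic reference of
# 114 nt (they do NOT describe any real strain); supply your own template
# for real analyses. Two rows sharing a helix name are the 5' and 3'
# strands of that hairpin and pair antiparallel.
helix	start	end	partner_helix
E23_1	7	11	E23_1
E23_1	16	20	E23_1
E23_2	25	29	E23_2
E23_2	34	38	E23_2
E23_4	43	47	E23_4
E23_4	52	56	E23_4
E23_7	61	65	E23_7
E23_7	70	74	E23_7
E23_9	79	83	E23_9
E23_9	88	92	E23_9
E23_13	97	101	E23_13
E23_13	106	110	E23_13
V4_tail	111	114	
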