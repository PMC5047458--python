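gene	exon_1	exon_2	exon_3	exon_4	exon_5	exon_6	exon_7	exon_8	exon_9	exon_10	exon_11	exon_12	exon_13	exon_14	aa_homology_pct
gamma-PLE	52	208	145	134	154	105	105	39	141	81	148	132	73	181
PLE-1	52	208	145	134	154	105	105	39	141	81	148	132	73	181	99
PLE-B9	52	208	145	134	154	105	105	39	141	81	148	132	73	181	96
PLE-C4	52	208	145	134	154	105	105	39	141	81	148	132	73	181	96
PLE-G2	52	208	145	134	154	105	105	39	141	81	148	132	73	181	98
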