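exon_id	0002-HAE-001	0058-HAE-001	0045-HAE-001	0046-HAE-001
exon1	1.52	2.01	1.21	1.99
exon2	4.14	4.04	5.01	5.12
exon3	2.25	2.11	2.45	2.06
exon4	1.77	1.53	0.86	1.96
exon5	1.29	1.06	1.35	1.57
exon6	7.84	5.79	1.28	1.45
exon7	1.11	1.33	1.49	1.09
exon8	1.11	1.65	1.26	0.95
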