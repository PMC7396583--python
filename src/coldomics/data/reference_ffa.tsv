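# Published 22-component free-fatty-acid panel means (ng mg^-1) for peanut cultivars
# NH5 and FH18, control vs 24 h cold.
name	NH5-control	NH5-cold	FH18-control	FH18-cold
C14:0	0.39	0.37	0.20	0.37
C14:1	0.95	0.91	0.37	0.34
C16:0	151.87	131.96	149.52	144.61
C16:1	51.29	41.41	51.14	53.16
C18:0	213.37	195.57	194.53	195.45
C18:1	59.60	51.95	58.82	58.31
C18:2	83.50	117.37	79.13	99.19
C18:3	164.18	211.32	166.05	186.73
C20:0	2.73	1.89	2.07	1.39
C20:1	0.53	1.14	0.67	0.55
C20:2	0.15	0.27	0.22	0.20
C20:3	56.72	62.60	1.08	0.80
C20:4	81.03	84.53	65.95	33.33
C20:5	0.31	0.38	0.41	0.35
C22:0	1.78	2.11	0.21	0.20
C22:1	0.34	0.55	0.43	0.42
C22:2	0.41	0.48	0.49	0.43
C22:4	1.17	1.34	1.36	1.21
C22:5	2.53	3.04	2.97	2.64
C22:6	2.55	2.89	2.99	2.63
C24:0	1.89	1.46	1.47	3.48
C24:1	0.63	0.72	0.67	0.60
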