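# Published per-class double-bond-index reference values (membrane lipids, 15 classes)
# for peanut cultivars NH5 (cold-tolerant) and FH18 (cold-sensitive), control vs 24 h cold,
# with the published relative-change columns.
class	NH5-control	NH5-cold	FH18-control	FH18-cold	rc_NH5	rc_FH18
MGDG	3.3534	2.8792	3.2965	2.2921	-0.1414	-0.3047
DGDG	0.6750	1.4135	0.7822	1.0660	1.0941	0.3628
SQDG	0.0084	0.0125	0.0086	0.0072	0.4881	-0.1628
PA	0.0195	0.0339	0.0174	0.0262	0.7385	0.5057
PC	0.2061	0.2271	0.2183	0.2349	0.1019	0.0760
PE	0.1911	0.1921	0.2279	0.2179	0.0052	-0.0439
PG	0.3981	0.4720	0.4464	0.4824	0.1856	0.0806
PI	0.0069	0.0098	0.0064	0.0086	0.4203	0.3438
PS	0.0010	0.0017	0.0013	0.0014	0.7000	0.0769
CL	0.0109	0.0130	0.0083	0.0117	0.1927	0.4096
Sph	0.0024	0.0035	0.0028	0.0030	0.4583	0.0714
Cer	0.0002	0.0003	0.0002	0.0003	0.2827	0.3074
PhytoCer	0.0003	0.0004	0.0003	0.0004	0.3333	0.3333
GluCer	0.0004	0.0006	0.0004	0.0004	0.5000	0.0000
S1P	0.0000	0.0000	0.0000	0.0000	0.0000	0.0000
Total	4.8736	5.2594	5.0170	4.3524	0.0792	-0.1325
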