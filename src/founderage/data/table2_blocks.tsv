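label_rsid	shared_chromosomes	fn_em	fn_chm	theta	n_snps	pr_em	pr_chm
rs12403629	4	0.01042	0.01042	0.01242	10	0.06781	0.06781
rs345292	6	0.01042	0.01042	0.01068	13	0.00134	0.00023
rs17020437	8	0.12489	0.06510	0.01009	6	0.26401	0.27172
rs12034547	10	0.16613	0.09782	0.00858	8	0.16613	0.17319
rs1333130	14	0.01042	0.01042	0.00130	24	0.00027	0.00027
CLCC1-MUTATION	18			0	9		
rs587727	16	0.57753	0.51823	0.00192	2	0.19910	0.31771
rs17014495	12	0.01042	0.01042	0.00221	17	0.00010	0.00010
rs12239350	6	0.01238	0.00977	0.00828	4	0.08626	0.14123
rs11102121	2	0.22394	0.22656	0.01522	2	0.51046	0.50521
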