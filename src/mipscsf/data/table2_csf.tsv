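time_min	blood_ml	rabbit_1	rabbit_2	rabbit_3	rabbit_4	rabbit_5	rabbit_6	rabbit_7	rabbit_8
6	0.33	1.0949	0.9156	0.6936	0.6872	0.687	0.6962	0.7474	0.8276
12	0.66	1.0796	0.8273	0.5925	0.6856	0.6805	0.6604	0.6506	0.7862
18	1.00	1.0653	0.8041	0.5285	0.6861	0.6344	0.5058	0.5418	0.7504
24	1.33	0.9959	0.7591	0.4584	0.6781	0.638	0.4289	0.4715	0.5819
30	1.66	0.8001	0.7636	0.3889	0.6735	0.6028	0.2732	0.3792	0.4842
36	2.00	0.6769	0.7321	0.3485	0.6555	0.6171	0.1839	0.2794	0.3974
42	2.33	0.6751	0.6962	0.3565	0.636	0.6054	0.1674	0.2363	0.3875
48	2.66	0.6225	0.6296	0.3078	0.622	0.5782	0.191	0.2776	0.3766
54	3.00	0.5702	0.6239	0.2885	0.6219	0.5596	0.1408	0.278	0.3629
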