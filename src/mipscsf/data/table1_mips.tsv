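time_min	blood_ml	rabbit_1	rabbit_2	rabbit_3	rabbit_4	rabbit_5	rabbit_6	rabbit_7	rabbit_8
6	0.33	100.2652	99.3756	99.7284	99.873	99.925	100.183	100.4718	100.4838
12	0.66	100.0558	98.1912	99.2334	99.171	99.171	99.7712	100.2348	100.233
18	1.00	99.48	97.2972	98.7932	98.778	98.778	99.3532	99.5864	99.7042
24	1.33	99.3584	96.927	98.6694	97.918	97.518	98.9064	99.4714	99.9792
30	1.66	99.2494	96.7842	98.4012	97.198	96.732	98.9564	99.547	100.417
36	2.00	99.507	97.0456	98.5262	97.772	96.832	98.9428	99.7418	100.6024
42	2.33	99.6194	97.2434	98.6388	97.405	97.333	98.685	100.315	101.0506
48	2.66	99.736	97.442	98.7586	98.817	97.986	99.218	100.016	101.0776
54	3.00	99.7768	97.83	98.7386	99.148	98.598	99.2944	100.3544	100.9496
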