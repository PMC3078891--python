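gene_symbol	tissue	rtpcr_p	rtpcr_log2fc	array_p	array_log2fc
Acadvl	heart	0.034	0.122	<0.001	0.747
Dnajc8	heart	0.008	0.270	<0.001	0.698
Gapdh	heart	0.140	n/a	0.008	0.620
Mbip	heart	0.580	n/a	0.001	0.884
Rbm3	heart	<0.001	2.349	<0.001	2.863
Rpl35a	heart	0.009	0.550	<0.001	1.857
Rpl7	heart	0.004	0.533	<0.001	1.243
Rps27	heart	0.009	0.600	0.001	0.720
Adk	heart	0.015	-0.164	0.006	-0.534
Aldh6a1	heart	<0.001	-0.974	0.001	-0.893
Ank1	heart	<0.001	-1.234	<0.001	-1.440
Gstz1	heart	0.031	-0.343	0.001	-0.605
Ube2v1	heart	0.001	-0.327	0.004	-0.600
Gpc3	liver	<0.001	2.307	<0.001	1.965
Rplp2	liver	<0.001	1.378	0.003	1.627
Cmtm8	liver	0.170	n/a	<0.001	1.525
Pc	liver	0.130	n/a	0.002	1.390
Crip2	liver	<0.001	1.064	0.001	1.285
A2m	liver	0.003	1.287	0.004	1.249
Rpl36	liver	0.002	0.963	0.004	1.223
Brp44l	liver	0.002	1.638	0.009	1.198
Naca	liver	<0.001	0.714	0.001	1.182
Fgfr2	liver	<0.001	1.055	<0.001	1.130
Tbca	liver	0.001	0.579	0.001	1.122
Rps6	liver	0.001	0.677	0.010	1.079
Comt	liver	<0.001	-0.741	0.001	-1.817
Arg1	liver	0.016	-1.418	0.009	-2.050
Phyh	liver	0.002	-1.328	0.004	-2.105
Tinag	liver	<0.001	-1.822	<0.001	-2.141
Ugt3a2	liver	<0.001	-4.034	<0.001	-2.949
Fmo5	liver	0.001	-2.631	0.002	-3.002
Pitrm1	liver	0.027	-0.421	0.001	-3.360
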