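category	gene_symbol	p_liver	log2fc_liver	p_heart	log2fc_heart
fatty_acid_catabolism	Aarsd1	0.006	0.638	0.006	0.838
fatty_acid_catabolism	Acadm	0.001	0.510	<0.001	1.138
fatty_acid_catabolism	Acadvl	0.001	0.842	<0.001	0.747
fatty_acid_catabolism	Hadha	0.007	0.586	0.008	0.556
protein_biosynthesis	Rps18	0.001	0.899	0.002	1.144
protein_biosynthesis	Rps29	0.006	0.802	0.001	0.843
protein_biosynthesis	Rbm3	<0.001	2.681	<0.001	2.863
protein_biosynthesis	Rpl18a	<0.001	0.606	0.002	0.607
protein_biosynthesis	Rpl22	0.006	1.398	0.004	0.923
protein_biosynthesis	Rpl24	0.005	0.935	0.003	0.725
protein_biosynthesis	Rpl27a	0.004	1.349	0.008	0.927
protein_biosynthesis	Rpl30	0.004	0.862	0.002	1.010
protein_biosynthesis	Rpl35a	0.001	0.937	<0.001	1.857
protein_biosynthesis	Rpl7	0.008	0.767	<0.001	1.243
protein_biosynthesis	Rplp2	0.003	1.627	0.001	0.732
protein_biosynthesis	Rps23	<0.001	1.213	0.001	1.793
protein_biosynthesis	Rps24	0.008	0.802	0.002	1.000
amino_acid_catabolism	Aldh6a1	0.006	-1.086	0.001	-0.893
amino_acid_catabolism	Got1	<0.001	-1.014	0.002	-0.644
amino_acid_catabolism	Lap3	0.008	-0.943	0.001	-0.771
other	Cd2bp2	0.005	0.981	0.008	0.614
other	Cdk2	0.001	0.755	0.005	0.827
other	Cd2bp2	0.005	0.981	0.008	0.614
other	Hnrnpa1	0.004	1.418	0.006	1.048
other	St7	0.001	0.909	0.003	0.965
other	Tinp1	0.010	0.678	<0.001	0.813
other	Cyp1a2	0.007	-2.290	0.005	-0.594
other	Phyh	0.004	-2.105	0.008	-0.865
other	Gbe1	0.007	-0.641	0.002	0.838
other	Glrx3	0.004	-0.595	0.001	1.011
other	Kif21a	0.010	1.000	0.009	-0.504
other	Mnat1	0.007	-0.675	0.006	1.067
other	Ppm1k	0.005	1.107	0.007	-0.615
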