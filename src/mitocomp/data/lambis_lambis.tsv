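gene	class	start	end	strand	start_codon	stop_codon
cox1	PCG	1	1536	+	ATG	TAA
cox2	PCG	1556	2242	+	ATG	TAA
trnD	tRNA	2241	2308	+
atp8	PCG	2309	2467	+	ATG	TAA
atp6	PCG	2472	3167	+	ATG	TAA
trnM	tRNA	3204	3271	-
trnY	tRNA	3290	3355	-
trnC	tRNA	3358	3422	-
trnW	tRNA	3424	3490	-
trnQ	tRNA	3492	3553	-
trnG	tRNA	3566	3632	-
trnE	tRNA	3634	3703	-
rrnS	rRNA	3708	4693	+
trnV	tRNA	4694	4760	+
rrnL	rRNA	4753	6147	+
trnL1	tRNA	6150	6218	+
trnL2	tRNA	6226	6294	+
nad1	PCG	6296	7237	+	ATG	TAG
trnP	tRNA	7247	7315	+
nad6	PCG	7320	7826	+	ATG	TAA
cytb	PCG	7836	8975	+	ATG	TAA
trnS2	tRNA	8990	9055	+
trnT	tRNA	9076	9141	-
nad4l	PCG	9150	9446	+	ATG	TAG
nad4	PCG	9440	10813	+	ATG	TAA
trnH	tRNA	10818	10884	+
nad5	PCG	10885	12612	+	ATG	TAA
trnF	tRNA	12654	12725	+
cox3	PCG	12780	13559	+	ATG	TAA
trnK	tRNA	13597	13666	+
trnA	tRNA	13693	13763	+
trnR	tRNA	13774	13842	+
trnN	tRNA	13854	13923	+
trnI	tRNA	13925	13992	+
nad3	PCG	13994	14347	+	ATG	TAA
trnS1	tRNA	14351	14418	+
nad2	PCG	14407	15477	+	ATC	TAG
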