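gene	class	start	end	strand	start_codon	stop_codon
cox1	PCG	1	1536	+	ATG	TAG
cox2	PCG	1556	2242	+	ATG	TAA
trnD	tRNA	2241	2308	+
atp8	PCG	2309	2467	+	ATG	TAA
atp6	PCG	2470	3165	+	ATG	TAA
trnM	tRNA	3202	3269	-
trnY	tRNA	3288	3353	-
trnC	tRNA	3356	3420	-
trnW	tRNA	3422	3488	-
trnQ	tRNA	3490	3551	-
trnG	tRNA	3564	3630	-
trnE	tRNA	3632	3701	-
rrnS	rRNA	3707	4684	+
trnV	tRNA	4685	4751	+
rrnL	rRNA	4737	6127	+
trnL1	tRNA	6134	6202	+
trnL2	tRNA	6212	6280	+
nad1	PCG	6282	7223	+	ATG	TAG
trnP	tRNA	7234	7301	+
nad6	PCG	7303	7809	+	ATG	TAA
cytb	PCG	7821	8960	+	ATG	TAA
trnS2	tRNA	8975	9040	+
trnT	tRNA	9059	9125	-
nad4l	PCG	9135	9431	+	ATG	TAG
nad4	PCG	9425	10798	+	GTG	TAA
trnH	tRNA	10808	10874	+
nad5	PCG	10875	12602	+	ATG	TAA
trnF	tRNA	12634	12702	+
cox3	PCG	12756	13535	+	ATG	TAA
trnK	tRNA	13574	13643	+
trnA	tRNA	13671	13742	+
trnR	tRNA	13754	13822	+
trnN	tRNA	13835	13901	+
trnI	tRNA	13904	13971	+
nad3	PCG	13973	14326	+	ATG	TAA
trnS1	tRNA	14329	14396	+
nad2	PCG	14385	15455	+	ATC	TAG
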