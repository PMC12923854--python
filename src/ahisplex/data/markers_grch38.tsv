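rsid	chrom	pos	ref_allele	alt_allele	probe_strand	counted_allele	variant_class	global_maf	trait_tags	may_be_absent
rs16891982	5	33951588	C	G	reverse	C	snp	0.28	hair,skin	
rs28777	5	33958854	A	C	forward	C	snp	0.094	hair,skin	
rs12203592	6	396321	C	T	forward	T	snp	0.17	eye,hair,skin	
rs4959270	6	457718	C	A	forward	A	snp	0.43	hair	
rs683	9	12709305	A	C	reverse	G	snp	0.44	hair,skin	
rs10756819	9	16858083	G	A	forward	A	snp	0.42	skin	
rs1042602	11	89178529	C	A	forward	A	snp	0.23	hair,skin	
rs1393350	11	89277878	G	A	forward	A	snp	0.22	eye,hair,skin	
rs1126809	11	89284793	G	A	forward	A	snp	0.21	hair,skin	
rs12821256	12	88934558	T	C	reverse	G	snp	0.11	hair	
rs12896399	14	92307319	G	T	forward	T	snp	0.44	eye,hair	
rs2402130	14	92334859	A	G	forward	G	snp	0.36	hair	
rs17128291	14	92416482	A	G	reverse	C	snp	0.15	skin	
rs12441727	15	27781483	G	A	forward	A	snp	0.11	skin	
rs1545397	15	27942626	A	T	forward	T	snp	0.24	skin	
rs1800414	15	27951891	T	C	forward	C	snp	0.06	skin	
rs1800407	15	27985172	C	T	reverse	A	snp	0.05	eye,hair	
rs1470608	15	28042975	G	T	reverse	A	snp	0.17	skin	
rs1129038	15	28111713	C	T	reverse	A	snp	0.26	eye,skin	
rs12913832	15	28120472	A	G	reverse	T	snp	0.26	eye,hair,skin	
rs2238289	15	28128866	T	C	forward	C	snp	0.19	skin	
rs6497292	15	28251049	T	C	forward	C	snp	0.17	skin	
rs1667394	15	28285036	T	C	forward	C	snp	0.21	eye,hair	
rs1426654	15	48134287	A	G	forward	G	snp	0.35	skin	
rs3114908	16	89317316	C	T	forward	T	snp	0.35	skin	
rs3212355	16	89912794	C	T	reverse	A	snp	0.13	hair	
rs312262906	16	89919344	A	AA	forward	A	single_base_dup	0.00078	hair,mc1r	
rs1805005	16	89919435	G	T	forward	T	snp	0.042	hair,mc1r	
rs1805006	16	89919509	C	A	forward	A	snp	0.005	hair,mc1r	
rs2228479	16	89919531	G	A	forward	A	snp	0.0766	hair,mc1r	
rs11547464	16	89919682	G	A	forward	A	snp	0.008	hair,mc1r	
rs1805007	16	89919708	C	T	forward	T	snp	0.021	hair,mc1r	
rs201326893	16	89919713	C	A	forward	A	snp	0.0006	hair,mc1r	GRCh38,hg38
rs1110400	16	89919721	T	C	forward	C	snp	0.004	hair,mc1r	
rs1805008	16	89919735	C	T	forward	T	snp	0.013	hair,mc1r	
rs885479	16	89919745	G	A	forward	A	snp	0.183	hair,mc1r	
rs1805009	16	89920199	G	C	forward	C	snp	0.0095	hair,mc1r	
rs8051733	16	89957797	A	G	reverse	C	snp	0.18	skin	
rs6059655	20	34077942	G	A	forward	A	snp	0.09	skin	
rs6119471	20	34197406	G	C	forward	C	snp	0.14	skin	
rs2378249	20	34630286	A	G	forward	G	snp	0.15	hair	
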