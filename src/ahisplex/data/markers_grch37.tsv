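rsid	chrom	pos	ref_allele	alt_allele	probe_strand	counted_allele	variant_class	global_maf	trait_tags	may_be_absent
rs16891982	5	33951693	C	G	reverse	C	snp	0.28	hair,skin	
rs28777	5	33958959	A	C	forward	C	snp	0.094	hair,skin	
rs12203592	6	396321	C	T	forward	T	snp	0.17	eye,hair,skin	
rs4959270	6	457748	C	A	forward	A	snp	0.43	hair	
rs683	9	12709305	A	C	reverse	G	snp	0.44	hair,skin	
rs10756819	9	16858084	G	A	forward	A	snp	0.42	skin	
rs1042602	11	88911696	C	A	forward	A	snp	0.23	hair,skin	
rs1393350	11	89011046	G	A	forward	A	snp	0.22	eye,hair,skin	
rs1126809	11	89017961	G	A	forward	A	snp	0.21	hair,skin	
rs12821256	12	89328335	T	C	reverse	G	snp	0.11	hair	
rs12896399	14	92773663	G	T	forward	T	snp	0.44	eye,hair	
rs2402130	14	92801203	A	G	forward	G	snp	0.36	hair	
rs17128291	14	92882826	A	G	reverse	C	snp	0.15	skin	
rs12441727	15	28026629	G	A	forward	A	snp	0.11	skin	
rs1545397	15	28187772	A	T	forward	T	snp	0.24	skin	
rs1800414	15	28197037	T	C	forward	C	snp	0.06	skin	
rs1800407	15	28230318	C	T	reverse	A	snp	0.05	eye,hair	
rs1470608	15	28288121	G	T	reverse	A	snp	0.17	skin	
rs1129038	15	28356859	C	T	reverse	A	snp	0.26	eye,skin	
rs12913832	15	28365618	A	G	reverse	T	snp	0.26	eye,hair,skin	
rs2238289	15	28374012	T	C	forward	C	snp	0.19	skin	
rs6497292	15	28496195	T	C	forward	C	snp	0.17	skin	
rs1667394	15	28530182	T	C	forward	C	snp	0.21	eye,hair	
rs1426654	15	48426484	A	G	forward	G	snp	0.35	skin	
rs3114908	16	89383725	C	T	forward	T	snp	0.35	skin	
rs3212355	16	89979203	C	T	reverse	A	snp	0.13	hair	
rs312262906	16	89985753	A	AA	forward	A	single_base_dup	0.00078	hair,mc1r	
rs1805005	16	89985844	G	T	forward	T	snp	0.042	hair,mc1r	
rs1805006	16	89985918	C	A	forward	A	snp	0.005	hair,mc1r	
rs2228479	16	89985940	G	A	forward	A	snp	0.0766	hair,mc1r	
rs11547464	16	89986091	G	A	forward	A	snp	0.008	hair,mc1r	
rs1805007	16	89986117	C	T	forward	T	snp	0.021	hair,mc1r	
rs201326893	16	89986122	C	A	forward	A	snp	0.0006	hair,mc1r	GRCh38,hg38
rs1110400	16	89986130	T	C	forward	C	snp	0.004	hair,mc1r	
rs1805008	16	89986144	C	T	forward	T	snp	0.013	hair,mc1r	
rs885479	16	89986154	G	A	forward	A	snp	0.183	hair,mc1r	
rs1805009	16	89986608	G	C	forward	C	snp	0.0095	hair,mc1r	
rs8051733	16	90024206	A	G	reverse	C	snp	0.18	skin	
rs6059655	20	32665748	G	A	forward	A	snp	0.09	skin	
rs6119471	20	32785212	G	C	forward	C	snp	0.14	skin	
rs2378249	20	33218090	A	G	forward	G	snp	0.15	hair	
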