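chrom	length
5	180915260
6	171115067
9	141213431
11	135006516
12	133851895
14	107349540
15	102531392
16	90354753
20	63025520
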