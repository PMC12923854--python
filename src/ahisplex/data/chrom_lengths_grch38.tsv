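chrom	length
5	181538259
6	170805979
9	138394717
11	135086622
12	133275309
14	107043718
15	101991189
16	90338345
20	64444167
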