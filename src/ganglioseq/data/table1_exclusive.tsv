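gene_id	symbol	exclusive_drg	exclusive_tg
ENSMUSG00000020123	Avpr1a	false	true
ENSMUSG00000038112	AW551984	true	false
ENSMUSG00000063415	Cyp26b1	true	false
ENSMUSG00000029054	Gabrd	false	true
ENSMUSG00000078706	Gm53	true	false
ENSMUSG00000043219	Hoxa6	true	false
ENSMUSG00000038236	Hoxa7	true	false
ENSMUSG00000038227	Hoxa9	true	false
ENSMUSG00000000938	Hoxa10	true	false
ENSMUSG00000048763	Hoxb3	true	false
ENSMUSG00000038700	Hoxb5	true	false
ENSMUSG00000000690	Hoxb6	true	false
ENSMUSG00000038721	Hoxb7	true	false
ENSMUSG00000001661	Hoxc6	true	false
ENSMUSG00000001657	Hoxc8	true	false
ENSMUSG00000036139	Hoxc9	true	false
ENSMUSG00000022484	Hoxc10	true	false
ENSMUSG00000027102	Hoxd8	true	false
ENSMUSG00000043342	Hoxd9	true	false
ENSMUSG00000050368	Hoxd10	true	false
ENSMUSG00000028033	Kcnq5	true	false
ENSMUSG00000049112	Oxtr	false	true
ENSMUSG00000005268	Prlr	true	false
ENSMUSG00000026475	Rgsl6	false	true
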