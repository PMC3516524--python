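# Long-range LD / inversion regions commonly excluded before genotype PCA (hg19).
chr1	48000000	52000000
chr2	86000000	100500000
chr2	134500000	138000000
chr2	183000000	190000000
chr3	47500000	50000000
chr3	83500000	87000000
chr3	89000000	97500000
chr5	44500000	50500000
chr5	98000000	100500000
chr5	129000000	132000000
chr5	135500000	138500000
chr6	25000000	35000000
chr6	57000000	64000000
chr6	140000000	142500000
chr7	55000000	66000000
chr8	7000000	13000000
chr8	43000000	50000000
chr8	112000000	115000000
chr10	37000000	43000000
chr11	46000000	57000000
chr11	87500000	90500000
chr12	33000000	40000000
chr12	109500000	112000000
chr20	32000000	34500000
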