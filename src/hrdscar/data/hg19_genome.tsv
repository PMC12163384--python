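chrom	length	centromere_start	centromere_end
chr1	249250621	121500001	128900000
chr2	243199373	90500001	96800000
chr3	198022430	87900001	93900000
chr4	191154276	48200001	52700000
chr5	180915260	46100001	50700000
chr6	171115067	58700001	63300000
chr7	159138663	58000001	61700000
chr8	146364022	43100001	48100000
chr9	141213431	47300001	50700000
chr10	135534747	38000001	42300000
chr11	135006516	51600001	55700000
chr12	133851895	33300001	38200000
chr13	115169878	16300001	19500000
chr14	107349540	16100001	19100000
chr15	102531392	15800001	20700000
chr16	90354753	34600001	38600000
chr17	81195210	22200001	25800000
chr18	78077248	15400001	19000000
chr19	59128983	24400001	28600000
chr20	63025520	25600001	29400000
chr21	48129895	10900001	14300000
chr22	51304566	12200001	17900000
chrX	155270560	58100001	63000000
chrY	59373566	11600001	13400000
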