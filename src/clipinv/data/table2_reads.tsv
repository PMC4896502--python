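pair_index	read_id	sequence	aln_nts	sc_nts	aln_start	aln_end	aln_strand	sc_start	sc_end	sc_strand
1	HWI-ST1297:143:H8A5HADXX:2:1211:13013:74367	AAGATGTTTTACTCTGCAATAAAATTTTGTACAATCTAACATTCATGAAAGAGGGAAATAAGTGGATTTTGCAAAGAATATTCACCAAGACCTTTGTTTAATTTAAAATAGTCTTCTGCAACTTGATTTTGTTCACCCAAGGGTATGTTTTCAAGATTCATCTATATTGTTGCTT	102	73	93599431	93599532	+	27762423	27762351	-
2	HWI-ST1297:143:H8A5HADXX:2:2216:6929:62067	TTACATTAGAGTATTTGCATTAAAGATGTTTTACTCTGCAATAAAATTTTGTACAATCTAACATTCATGAAAGAGGGAAATAAGTGGATTTTGCAAAGAATATTCACCAAGACCTTTGTTTAATTTAAAATAGTCTTCTGCAACTTGATTTTGTTCACCCAAGGGTATGTTTTCA	124	51	93599409	93599532	+	27762423	27762373	-
3	HWI-ST1297:143:H8A5HADXX:2:2106:11510:54958	ACAGCAGTGAAAATGAATGTGTGAGCTACAGCTACAAGCAACAATATAGATGAATCTTGAAAACATACCCTTGGGTGAACAAAATCAAGTTGCAGAAGACTATTTTAAATTAAACAAAGGTCTTGGTGAATATTCTTTGCAAAATCCACTTATTTCCCTCTTTCATGAATGTTAG	110	65	27762316	27762425	+	93599530	93599466	-
4	HWI-ST1297:143:H8A5HADXX:2:1205:16877:58763	AAATGAATGTGTGAGCTACAGCTACAAGCAACAATATAGATGAATCTTGAAAACATACCCTTGGGTGAACAAAATCAAGTTGCAGAAGACTATTTTAAATTAAACAAAGGTCTTGGTGAATATTCTTTGCAAAATCCACTTATTTCCCTCTTTCATGAATGTTAGATTGTACAAA	100	75	27762326	27762425	+	93599530	93599456	-
5	HWI-ST1297:143:H8A5HADXX:2:1102:3940:94914	GCATTAAAGATGTTTTACTCTGCAATAAAATTTTGTACAATCTAACATTCATGAAAGAGGGAAATAAGTGGATTTTGCAAAGAATATTCACCAAGACCTTTGTTTAATTTAAAATAGTCTTCTGCAACTTGATTTTGTTCACCCAAGGGTATGTTTTCAAGATTCATCTATATTG	108	67	93599425	93599532	+	27762423	27762357	-
6	HWI-ST1297:143:H8A5HADXX:2:1215:19689:22918	GGGAAATAAGTGGATTTTGCAAAGAATATTCACCAAGACCTTTGTTTAATTTAAAATAGTCTTCTGCAACTTGATTTTGTTCACCCAAGGGTATGTTTTCAAGATTCATCTATATTGTTGCTTGTAGCTGTAGCTCACACATTCATTTTCACTGCTGTATAAAATTCTATTGTGT	50	125	93599483	93599532	+	27762423	27762299	-
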