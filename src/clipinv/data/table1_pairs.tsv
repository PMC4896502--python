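pair_index	read_id	pos_1	strand_1	mapq_1	cigar_1	pos_2	strand_2	mapq_2	cigar_2	apparent_insert_size
1	HWI-ST1297:143:H8A5HADXX:2:1211:13013:74367	27762167	+	6	50M	93599431	+	60	102M73S	65837265
2	HWI-ST1297:143:H8A5HADXX:2:2216:6929:62067	27762258	+	53	50M	93599409	+	60	124M51S	65837152
3	HWI-ST1297:143:H8A5HADXX:2:2106:11510:54958	27762316	+	60	110M65S	93599416	+	60	50M	65837101
4	HWI-ST1297:143:H8A5HADXX:2:1205:16877:58763	27762326	+	60	100M75S	93599338	+	60	50M	65837013
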