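chromosome	probe	start_bp	stop_bp	n_oligos
chr1	Ms1.1	0	4440780	4800
chr1	Ms1.2	84374820	88815615	4800
chr2	Ms2.1	0	3837500	4800
chr2	Ms2.2	72912500	76750018	4800
chr3	Ms3.1	0	5020726	4800
chr3	Ms3.2	45186534	50207260	4800
chr3	Ms3.3	95393794	100414524	4800
chr4	Ms4.1	0	4697371	4800
chr4	Ms4.2	51671081	56368452	4800
chr4	Ms4.3	89250049	93947428	4800
chr5	Ms5.1	0	4208274	4800
chr5	Ms5.2	79957206	84165483	4800
chr6	Ms6.1	0	4478960	4800
chr6	Ms6.2	35831680	40310640	4800
chr6	Ms6.3	85100240	89579199	4800
chr7	Ms7.1	0	4732886	4800
chr7	Ms7.2	47328860	52061746	4800
chr7	Ms7.3	89924834	94657719	4800
chr8	Ms8.1	0	4362117	4800
chr8	Ms8.2	43621170	47983287	4800
chr8	Ms8.3	82880223	87242343	4800
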