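metric	sample	value
raw_reads	A_elongata	195890
raw_reads	Collozoum_sp	214475
raw_reads	S_streptacantha	220239
raw_reads	A_scolymantha	195070
cleaned_reads	A_elongata	138867
cleaned_reads	Collozoum_sp	121079
cleaned_reads	S_streptacantha	120924
cleaned_reads	A_scolymantha	126494
unigenes	A_elongata	14210
unigenes	Collozoum_sp	42784
unigenes	S_streptacantha	25590
unigenes	A_scolymantha	42251
contigs	A_elongata	3252
contigs	Collozoum_sp	4888
contigs	S_streptacantha	3229
contigs	A_scolymantha	3243
average_length	A_elongata	362
average_length	Collozoum_sp	337
average_length	S_streptacantha	348
average_length	A_scolymantha	369
median_length	A_elongata	365
median_length	Collozoum_sp	324
median_length	S_streptacantha	338
median_length	A_scolymantha	378
gc_percent	A_elongata	46.3
gc_percent	Collozoum_sp	44.0
gc_percent	S_streptacantha	50.9
gc_percent	A_scolymantha	40.6
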