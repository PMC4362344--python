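row	sample	fraction	count
Total bacteria	A_elongata	rRNA	138
Total bacteria	A_elongata	mRNA	2077
Total bacteria	Collozoum_sp	rRNA	42
Total bacteria	Collozoum_sp	mRNA	1943
Total bacteria	S_streptacantha	rRNA	65
Total bacteria	S_streptacantha	mRNA	2254
Total bacteria	A_scolymantha	rRNA	85
Total bacteria	A_scolymantha	mRNA	2042
Total Rhizaria	A_elongata	rRNA	171
Total Rhizaria	A_elongata	mRNA	54
Total Rhizaria	Collozoum_sp	rRNA	25
Total Rhizaria	Collozoum_sp	mRNA	100
Total Rhizaria	S_streptacantha	rRNA	793
Total Rhizaria	S_streptacantha	mRNA	132
Total Rhizaria	A_scolymantha	rRNA	51
Total Rhizaria	A_scolymantha	mRNA	110
Total Alveolata	A_elongata	rRNA	22
Total Alveolata	A_elongata	mRNA	174
Total Alveolata	Collozoum_sp	rRNA	48
Total Alveolata	Collozoum_sp	mRNA	632
Total Alveolata	S_streptacantha	rRNA	15
Total Alveolata	S_streptacantha	mRNA	222
Total Alveolata	A_scolymantha	rRNA	23
Total Alveolata	A_scolymantha	mRNA	689
Total Heterokonts	A_elongata	rRNA	7
Total Heterokonts	A_elongata	mRNA	247
Total Heterokonts	Collozoum_sp	rRNA	5
Total Heterokonts	Collozoum_sp	mRNA	614
Total Heterokonts	S_streptacantha	rRNA	12
Total Heterokonts	S_streptacantha	mRNA	425
Total Heterokonts	A_scolymantha	rRNA	25
Total Heterokonts	A_scolymantha	mRNA	852
Total eukaryotes	A_elongata	rRNA	270
Total eukaryotes	A_elongata	mRNA	4588
Total eukaryotes	Collozoum_sp	rRNA	103
Total eukaryotes	Collozoum_sp	mRNA	15107
Total eukaryotes	S_streptacantha	rRNA	1120
Total eukaryotes	S_streptacantha	mRNA	9687
Total eukaryotes	A_scolymantha	rRNA	318
Total eukaryotes	A_scolymantha	mRNA	18724
No hits	A_elongata	rRNA	0
No hits	A_elongata	mRNA	5782
No hits	Collozoum_sp	rRNA	0
No hits	Collozoum_sp	mRNA	22583
No hits	S_streptacantha	rRNA	0
No hits	S_streptacantha	mRNA	10238
No hits	A_scolymantha	rRNA	0
No hits	A_scolymantha	mRNA	18303
Not assigned	A_elongata	rRNA	0
Not assigned	A_elongata	mRNA	1353
Not assigned	Collozoum_sp	rRNA	0
Not assigned	Collozoum_sp	mRNA	2988
Not assigned	S_streptacantha	rRNA	0
Not assigned	S_streptacantha	mRNA	1962
Not assigned	A_scolymantha	rRNA	0
Not assigned	A_scolymantha	mRNA	2754
Total	A_elongata	rRNA	408
Total	A_elongata	mRNA	13800
Total	Collozoum_sp	rRNA	145
Total	Collozoum_sp	mRNA	42631
Total	S_streptacantha	rRNA	1185
Total	S_streptacantha	mRNA	24170
Total	A_scolymantha	rRNA	403
Total	A_scolymantha	mRNA	41846
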