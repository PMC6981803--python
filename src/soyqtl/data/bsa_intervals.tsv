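trait	name	chrom	start_bp	end_bp	size_mb_published
PH	qPH-n-1	Gm03	4390000	12070000	7.68
PH	qPH-n-2	Gm03	15860000	30880000	15.02
PH	qPH-c1-3	Gm04	49640000	52380000	2.74
PH	qPH-k-2	Gm09	39480000	41020000	1.54
PH	qPH-k-3	Gm09	44280000	48060000	3.78
PH	qPH-o-5	Gm10	46350000	47340000	0.99
NNMS	qMS-c1-1	Gm04	50350000	52380000	2.03
NNMS	qMS-c2-3	Gm06	47290000	48010000	0.72
NNMS	qMS-c2-4	Gm06	48040000	48040000	0.00
NNMS	qMS-c2-5	Gm06	48740000	49070000	0.33
NNMS	qMS-c2-6	Gm06	49350000	50520000	1.17
NNMS	qMS-j-3	Gm16	2010000	5360000	3.35
NNMS	qMS-j-4	Gm16	31390000	37880000	6.49
NNMS	qMS-D2-1	Gm17	3160000	9210000	6.05
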