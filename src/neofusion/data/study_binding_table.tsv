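peptide	source	allele	ic50_nm
FPRKLYFL	nsfp1_truncation	HLA-B*42:01	4
FPRKLYFL	nsfp1_truncation	HLA-B*08:01	10
FPRKLYFL	nsfp1_truncation	HLA-A*32:07	16
FPRKLYFL	nsfp1_truncation	HLA-A*68:23	20
FPRKLYFL	nsfp1_truncation	HLA-B*44:01	24
FPRKLYFL	nsfp1_truncation	HLA-B*07:02	43
FPRKLYFL	nsfp1_truncation	HLA-C*14:02	51
FPRKLYFL	nsfp1_truncation	HLA-B*53:01	62
FPRKLYFL	nsfp1_truncation	HLA-C*08:02	70
FPRKLYFL	nsfp1_truncation	HLA-B*07:01	93
FPRKLYFL	nsfp1_truncation	HLA-B*15:02	146
FPRKLYFL	nsfp1_truncation	HLA-C*07:02	152
FPRKLYFL	nsfp1_truncation	HLA-A*32:15	169
FPRKLYFL	nsfp1_truncation	HLA-C*03:04	260
FPRKLYFL	nsfp1_truncation	HLA-C*03:03	279
KFPRKLYF	nsfp1_truncation	HLA-A*24:03	2
KFPRKLYF	nsfp1_truncation	HLA-A*68:23	10
KFPRKLYF	nsfp1_truncation	HLA-A*32:07	15
KFPRKLYF	nsfp1_truncation	HLA-C*14:02	16
KFPRKLYF	nsfp1_truncation	HLA-C*03:03	41
KFPRKLYF	nsfp1_truncation	HLA-B*15:02	53
KFPRKLYF	nsfp1_truncation	HLA-C*07:02	56
KFPRKLYF	nsfp1_truncation	HLA-A*32:15	71
KFPRKLYF	nsfp1_truncation	HLA-B*15:03	161
KFPRKLYF	nsfp1_truncation	HLA-A*23:01	203
KFPRKLYF	nsfp1_truncation	HLA-B*44:01	279
KFPRKLYF	nsfp1_truncation	HLA-A*24:01	407
KFPRKLYF	nsfp1_truncation	HLA-B*27:02	410
LENDIKPK	nsfp1_truncation	HLA-A*68:23	250
LENDIKPK	nsfp1_truncation	HLA-C*07:02	316
IKPKFPRK	nsfp1_truncation	HLA-A*68:23	69
IKPKFPRK	nsfp1_truncation	HLA-C*07:02	124
IKPKFPRK	nsfp1_truncation	HLA-A*32:07	159
IKPKFPRK	nsfp1_truncation	HLA-A*30:01	260
PKFPRKLY	nsfp1_truncation	HLA-C*07:02	75
KPKFPRKL	nsfp1_truncation	HLA-B*42:01	44
KPKFPRKL	nsfp1_truncation	HLA-C*07:02	50
KPKFPRKL	nsfp1_truncation	HLA-B*07:02	125
KPKFPRKL	nsfp1_truncation	HLA-B*07:01	326
KPKFPRKL	nsfp1_truncation	HLA-A*32:07	477
DIKPKFPR	nsfp1_truncation	HLA-A*33:01	7
DIKPKFPR	nsfp1_truncation	HLA-C*07:02	100
DIKPKFPR	nsfp1_truncation	HLA-A*68:23	127
DIKPKFPR	nsfp1_truncation	HLA-A*68:01	210
DIKPKFPR	nsfp1_truncation	HLA-A*32:07	362
PRKLYFLH	nsfp1_truncation	HLA-A*68:23	25
PRKLYFLH	nsfp1_truncation	HLA-C*14:02	35
PRKLYFLH	nsfp1_truncation	HLA-A*32:07	48
NDIKPKFP	nsfp1_truncation	HLA-B*44:01	40
NDIKPKFP	nsfp1_truncation	HLA-A*68:23	84
NDIKPKFP	nsfp1_truncation	HLA-A*32:07	115
NDIKPKFP	nsfp1_truncation	HLA-C*08:02	262
NDIKPKFP	nsfp1_truncation	HLA-C*07:02	271
NDIKPKFP	nsfp1_truncation	HLA-A*32:15	332
ENDIKPKF	nsfp1_truncation	HLA-C*07:02	39
ENDIKPKF	nsfp1_truncation	HLA-B*44:01	75
ENDIKPKF	nsfp1_truncation	HLA-C*08:02	81
ENDIKPKF	nsfp1_truncation	HLA-A*32:07	169
ENDIKPKF	nsfp1_truncation	HLA-A*68:23	203
MISNQNFQ	lrrc37a2_truncation	HLA-A*68:23	8
MISNQNFQ	lrrc37a2_truncation	HLA-A*32:07	32
MISNQNFQ	lrrc37a2_truncation	HLA-A*32:15	168
MISNQNFQ	lrrc37a2_truncation	HLA-C*03:03	492
ISNQNFQG	lrrc37a2_truncation	HLA-A*68:23	30
ISNQNFQG	lrrc37a2_truncation	HLA-A*32:07	59
ISNQNFQG	lrrc37a2_truncation	HLA-C*12:03	132
ISNQNFQG	lrrc37a2_truncation	HLA-A*32:15	209
SNQNFQGN	lrrc37a2_truncation	HLA-A*68:23	132
SNQNFQGN	lrrc37a2_truncation	HLA-A*32:07	156
NQNFQGNY	lrrc37a2_truncation	HLA-A*30:02	13
NQNFQGNY	lrrc37a2_truncation	HLA-A*68:23	94
NQNFQGNY	lrrc37a2_truncation	HLA-B*15:01	139
NQNFQGNY	lrrc37a2_truncation	HLA-A*32:07	141
NQNFQGNY	lrrc37a2_truncation	HLA-A*32:15	335
QNFQGNYI	lrrc37a2_truncation	HLA-A*68:23	23
QNFQGNYI	lrrc37a2_truncation	HLA-A*32:07	36
QNFQGNYI	lrrc37a2_truncation	HLA-A*32:15	160
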