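gene	alleles	guide	n_genotyped	n_ki	lethal	marker
clik-1	sy1084 and sy1085	CTCTGGCTCTTGGTTCTCGT	46	24	no	dpy-10
clik-2	sy1122 and sy1123	GTATCCTTGCTTCTTGTCCT	105	28	yes	dpy-10
clik-3	sy1082 and sy1083	GTCACGTGGTGTTCCGAAAC	46	6	no	dpy-10
clik-3	sy1086 and sy1087	ATTGCTTGGCACCTCGACGG	38	13	no	dpy-10
T05C3.2	sy1080 and sy1081	AGAACGAAACGCGCTAATGG	45	16	no	dpy-10
cul-3	sy1153 and s1154	ACTTTTGAAGCGTGCCATAC	40	12	yes	dpy-10
dlg-1	sy1155 and sy1156	ACACTCCTACAACAGTCGTC	46	17	yes	dpy-10
ubq-1	sy1157 and sy1158	AAAAACTATCACCCTGGAGG	19	2	yes	dpy-10
hpo-29	sy1159 and sy1160	ATCTCCGTTCATATGTCTGC	12	2	yes	dpy-10
Y106G6H.8	sy1076 and sy1077	AGGCCAGCCAGACGAATAAT	24	21	no	dpy-10
aex-2	sy1078 and sy1079	ATTACTGCAGCGACATGGGG	16	7	no	dpy-10
Y71H2AM.20	sy1176 and sy1177	TCTCCTAGCCAGCGTTCTTC	22	4	yes	dpy-10
set-16	sy1178 and sy1179	CTGACGTTGTTGCTGCATGG	23	7	yes	dpy-10
C01B10.10	sy1114 and sy1115	GCTCTGGGTCCATGTTGAAT	24	20	no	dpy-10
C56G2.15	sy1120 and sy1121	ACGACATTGGAGGGGACTGA	23	21	no	dpy-10
C01B10.4	sy1131 and sy1132	CATTTGGAAGGTGCAGAGAT	23	23	no	dpy-10
C23H4.2	sy1163 and sy1164	GCTTTGCAAACGGAACACTC	23	18	no	dpy-10
C04G6.4	sy1165 and sy1166	ATATTTGGCTGGAGAACTGG	24	15	no	unc-58
ttc-36	sy1167 and sy1168	CGAGAGAGAAGGTGTCGCGT	24	14	no	unc-58
ZC376.2	sy1170 and sy1171	GGAGGCGAAGGAGTATAAAG	24	19	no	dpy-10
cpn-4	sy1172 and sy1173	TGTTGAAGCTGGATACTTGT	24	13	no	dpy-10
Y55F3BL.4	sy1174 and sy1175	CTGGTCACTGGTAGAAAAGC	23	20	no	unc-58
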