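# Published per-gene TcGT recurrence counts in a colorectal cohort of 286
# patients with matched tumor and normal colon samples (N_tumor = N_normal
# = 286). nN / nT = number of normal / tumor samples with at least one
# passing TcGT of the gene; products = predicted protein-product classes.
gene	nN	nT	products
POU5F1B	11	186	canonical
HTR1D	9	175	canonical
SLCO1B3	6	159	N-trunc
CMTR1	2	149	C-trunc
ABLIM2	1	111	N-ext
NCALD	28	124	canonical
SLC22A3	25	119	N-trunc;N-C-trunc
PMPCB	7	94	N-C-trunc;out-of-frame;C-trunc
CAPN12	2	75	canonical;C-trunc
FGGY	8	80	canonical;N-trunc
TRAF2	8	80	canonical;N-ext
ATP5J2	13	85	canonical
RNF43	3	71	canonical;N-ext
EDAR	0	66	N-ext
TM9SF2	4	70	canonical
CEP72	25	91	N-trunc;N-C-trunc
TSSC1	9	73	N-trunc;C-ext
KRT8	7	67	N-ext
WFDC3	24	83	N-trunc
PALD1	16	74	canonical;C-trunc;out-of-frame
SBF2	12	69	out-of-frame;N-trunc
SPACA3	3	58	N-ext
MCCC2	6	61	out-of-frame;N-C-trunc
POMZP3	20	70	canonical;C-trunc
TNRC18	22	72	N-trunc;N-C-trunc
BMP7	12	62	out-of-frame
ABHD2	13	63	canonical
TGIF2	14	63	canonical
ST3GAL2	23	70	canonical
ZNF283	19	66	canonical;out-of-frame
ADAP1	16	63	canonical
CLSTN3	23	66	canonical
CLDN4	16	58	canonical
FAM110A	17	59	canonical
DAP3	27	67	N-trunc;out-of-frame
PTPDC1	27	67	canonical;N-trunc
PMFBP1	20	58	canonical;C-trunc;N-C-trunc
TXLNG	26	63	N-C-trunc
ZNF710	26	60	N-ext
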