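# surface	ncbi_gene_id  (official symbol listed before synonyms)
PTEN	5728
phosphatase and tensin homolog	5728
ROCK1	6093
TGFB1	7040
TGF-β1	7040
TGF-beta1	7040
TGF-b1	7040
transforming growth factor beta 1	7040
AKT1	207
p-AKT	207
AKT	207
EZH2	2146
EGFR	1956
epidermal growth factor receptor	1956
BMI1	648
XIAP	331
MT1	4489
MT1A	4489
IL-33	90865
IL33	90865
interleukin 33	90865
PPARG	5468
PPAR gamma	5468
PPAR-gamma	5468
PPARgamma	5468
PDCD4	27250
programmed cell death 4	27250
CDK6	1021
BCL2	596
Bcl-2	596
VEGFA	7422
VEGF	7422
MYC	4609
c-Myc	4609
KRAS	3845
CCND1	595
cyclin D1	595
ZEB1	6935
STAT3	6774
TIMP3	7078
SOX2	6657
E2F1	1869
NOTCH1	4851
SIRT1	23411
HMGA2	8091
CXCR4	7852
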