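# Illustrative (synthetic) RBP -> pentamer lookup table.
# The RBP names are real splicing regulators reported in SMN-depletion
# screens; the pentamer assignments here are simplified stand-ins drawn
# from each protein's commonly cited core recognition element, intended
# for demonstrations and tests.  Supply your own curated table for real
# analyses (columns: rbp, pentamer).
rbp	pentamer
SRSF10	AGAGA
SRSF10	AAGAA
hnRNP-L	ACACA
hnRNP-L	CACAC
hnRNP-LL	ACACA
RBM24	GTGTG
RBM24	TGTGT
SRSF1	GGAGG
PTBP1	TCTCT
PTBP1	CTCTC
NOVA1	TCATT
QKI	ACTAA
MBNL1	GCTTG
CELF1	TGTTT
FOX1	TGCAT
HuD	TTTAT
TIA1	TTTTA
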