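# Horse MSY gene catalog fixture (PARTLY SYNTHETIC).
# Marginal totals transcribe the published summary table: 52 genes/transcripts,
# 37 single-copy + 15 multi-copy, 174 total copies (37 + 137); categories
# 29 ancestral X-Y + 10 autosomal transposed + 10 Y-born novel + 2 PAR
# transposed + 1 autosomal transposed to PAB; ampliconic X-Y copy numbers
# HSFY=3, UBA1Y=8, CUL4BY=9, TSPY=13; ETSTY7=15 copies; expression marginals
# broad=29, testis-dominant=17, limited=1, none=4, tentative=1.
# Gene names not printed in the running text are placeholders (XY*, ATY*,
# YB*): per-gene rows for those are synthetic reconstructions consistent
# with the printed marginals only.
gene	category	copies	expression
SRY	ancestral X-Y	1	testis-dominant
RBMY	ancestral X-Y	1	testis-dominant
SYPY	ancestral X-Y	1	testis-dominant
XY22	ancestral X-Y	1	testis-dominant
AMELY	ancestral X-Y	1	limited
ZFY	ancestral X-Y	1	broad
TMSBY	ancestral X-Y	1	broad
OFD1Y	ancestral X-Y	1	broad
ZRSR2Y	ancestral X-Y	1	broad
SHROOM2Y	ancestral X-Y	1	broad
TBL1Y	ancestral X-Y	1	broad
ANOS1Y	ancestral X-Y	1	broad
STSY	ancestral X-Y	1	broad
NLGN4Y	ancestral X-Y	1	broad
TAB3Y	ancestral X-Y	1	broad
WWC3Y	ancestral X-Y	1	broad
DDX3Y	ancestral X-Y	1	broad
UTY	ancestral X-Y	1	broad
USP9Y	ancestral X-Y	1	broad
AP1S2Y	ancestral X-Y	1	broad
BCORY	ancestral X-Y	1	broad
ZBED1Y	ancestral X-Y	1	broad
XY23	ancestral X-Y	1	tentative
XY24	ancestral X-Y	1	none
XY25	ancestral X-Y	1	none
HSFY	ancestral X-Y	3	testis-dominant
UBA1Y	ancestral X-Y	8	testis-dominant
CUL4BY	ancestral X-Y	9	testis-dominant
TSPY	ancestral X-Y	13	testis-dominant
HSPA1LY	autosomal transposed	1	broad
ATY2	autosomal transposed	1	broad
ATY3	autosomal transposed	1	broad
ATY4	autosomal transposed	1	broad
ATY5	autosomal transposed	1	broad
ATY6	autosomal transposed	1	none
ATY7	autosomal transposed	1	none
ATYM1	autosomal transposed	4	broad
ATYM2	autosomal transposed	4	broad
ATYM3	autosomal transposed	4	broad
YBS1	Y-born novel	1	broad
YBS2	Y-born novel	1	broad
ETSTY7	Y-born novel	15	testis-dominant
YB1	Y-born novel	11	testis-dominant
YB2	Y-born novel	11	testis-dominant
YB3	Y-born novel	11	testis-dominant
YB4	Y-born novel	11	testis-dominant
YB5	Y-born novel	11	testis-dominant
YB6	Y-born novel	11	testis-dominant
YB7	Y-born novel	11	testis-dominant
ARSFY	PAR transposed	1	broad
ARSHY	PAR transposed	1	broad
XKR3Y	autosomal transposed to PAB	1	testis-dominant
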