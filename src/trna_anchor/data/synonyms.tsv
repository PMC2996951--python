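alias	token
COI	COI
CO1	COI
COX1	COI
COXI	COI
MT-CO1	COI
CYTOCHROME C OXIDASE SUBUNIT I	COI
CYTOCHROME C OXIDASE SUBUNIT 1	COI
CYTOCHROME OXIDASE SUBUNIT I	COI
TRNW	trnW
TRN-W	trnW
TRNA-TRP	trnW
TRNA-W	trnW
TRNC	trnC
TRN-C	trnC
TRNA-CYS	trnC
TRNA-C	trnC
TRNY	trnY
TRN-Y	trnY
TRNA-TYR	trnY
TRNA-Y	trnY
TRNQ	trnQ
TRNA-GLN	trnQ
TRNA-Q	trnQ
TRNA	trnA
TRNA-ALA	trnA
TRNN	trnN
TRNA-ASN	trnN
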