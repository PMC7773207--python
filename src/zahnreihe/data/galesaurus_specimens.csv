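specimen_id,taxon,bsl_mm,stage,max_l,max_r,mand_l,mand_r,source
FMNH PR 1774,galesaurus,62,juvenile,7,7,9,9,literature
NMP 581,galesaurus,64,juvenile,9,9,10?,–,anatomical
RC 845,galesaurus,69,subadult,10,9,11,11,uct
SAM-PK-K1119,galesaurus,72,subadult,8,9,9,?,anatomical
SAM-PK-K9956,galesaurus,73,subadult,–,9,–,–,anatomical
NMQR 655,galesaurus,~75,subadult,8,?,–,–,anatomical
AMNH FARB 2227,galesaurus,79,subadult,10,10,?,11,literature
BP/1/4714,galesaurus,81,subadult,11,11?,12,13,uct
BP/1/4602,galesaurus,88,subadult,10,10,11,11,uct
BP/1/3892,galesaurus,90,adult,9,9,–,–,literature
NMQR 1451,galesaurus,90,adult,10,10?,–,–,anatomical
NMQR 135,galesaurus,94,adult,9,9?,–,–,uct
NMQR 3340,galesaurus,~102,adult,10,10,–,–,anatomical
NMQR 3542,galesaurus,102,adult,11,11,15?,12,uct
BP/1/5064,galesaurus,103,adult,11,11,14,14,uct
SAM-PK-K10468,galesaurus,105,adult,9,10,11,10,uct
NMQR 860,galesaurus,114,adult,10,10,13,13,uct
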