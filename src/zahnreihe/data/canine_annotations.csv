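specimen_id,replacement_evidence,root
RC 845,true,closed
SAM-PK-K1119,true,closed
AMNH FARB 2227,true,closed
BP/1/4714,true,closed
BP/1/4602,true,closed
BP/1/3892,false,unknown
NMQR 1451,false,unknown
NMQR 135,false,open
NMQR 3340,false,unknown
NMQR 3542,false,open
BP/1/5064,false,open
SAM-PK-K10468,false,open
NMQR 860,false,open
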