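specimen_id,taxon,max_count,note
TM 83,galesaurus,12,largest published maxillary postcanine count; no basal skull length on record
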