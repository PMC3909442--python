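family_id,sample_id,subtype
031,031-1,Basal-like
031,031-2,Basal-like
018,018-1,HER2-enriched
018,018-2,HER2-enriched
017,017-1,LumA
017,017-2,LumA
029,029-1,LumA
029,029-2,LumA
029,029-3,LumA
042,042-1,LumA
042,042-2,LumA
024,024-1,LumB
024,024-2,LumB
030,030-1,LumB
030,030-2,LumB
034,034-1,LumB
034,034-2,LumB
027,027-1,Basal-like
027,027-2,LumB
006,006-1,LumA
006,006-2,Normal-like
014,014-1,LumA
014,014-2,LumB
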