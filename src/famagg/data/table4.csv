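family_id,sample_id,subtype
L101,L101-1,Basal-like
L101,L101-2,Basal-like
L414,L414-1,LumA
L414,L414-2,LumA
L505,L505-1,LumB
L505,L505-2,LumB
L99,L99-1,Basal-like
L99,L99-2,Normal-like
L99,L99-3,Normal-like
L16,L16-1,Basal-like
L16,L16-2,HER2-enriched
L16,L16-3,LumA
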