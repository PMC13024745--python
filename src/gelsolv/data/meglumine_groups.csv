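# Hand-curated fragmentation of meglumine (N-methyl-D-glucamine,
# C7H17NO5, 195.21 g/mol): CH3-NH-CH2-(CHOH)4-CH2-OH.
group,count
CH3,1
NH,1
CH2,2
CH,4
OH,5
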