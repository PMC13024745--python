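# Hand-curated fragmentation of sulindac (C20H17FO3S, 356.41 g/mol):
# 2-methyl-1H-indene core bearing an acetic-acid side chain, a ring
# fluorine, and an exocyclic benzylidene linked to a p-methylsulfinyl
# phenylene. The fused benzo ring (two fusion carbons + F carbon) is
# counted as a trisubstituted benzene; the cyclopentene carbons as
# three =C< plus one non-aromatic ring closure.
group,count
CH3,2
CH2,1
COOH,1
=CH-,1
=C<,3
phenylene,1
phenyl trisubstituted,1
F,1
S=O,1
ring (non-aromatic),1
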