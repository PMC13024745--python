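# Default group-contribution table: Hoftyzer-van Krevelen molar attraction
# constants (F_d, F_p in MPa^0.5 cm3/mol; E_h in J/mol) paired with Fedors
# (1974) molar-volume increments (V in cm3/mol). Negative V entries are the
# Fedors convention for branch carbons. "aromatic CH"/"aromatic C" are
# per-atom values derived from the phenyl/phenylene/trisubstituted-benzene
# aggregates (exactly consistent for F_d; F_p split evenly over ring atoms).
# "S=O" (sulfinyl) is a curated entry: dispersion as divalent S, polar term
# at nitrile level (comparable dipole moment), acceptor-only hydrogen
# bonding at ketone level, volume as S + O.
name,F_d,F_p,E_h,V
CH3,420,0,0,33.5
CH2,270,0,0,16.1
CH,80,0,0,-1.0
C,-70,0,0,-19.2
=CH2,400,0,0,28.5
=CH-,200,0,0,13.5
=C<,70,0,0,-5.5
aromatic CH,265,18.3,0,15.1
aromatic C,105,18.3,0,-3.9
phenyl,1430,110,0,71.4
phenylene,1270,110,0,52.4
phenyl trisubstituted,1110,176,0,33.4
F,220,640,500,18.0
Cl,450,550,400,24.0
CN,430,1100,2500,24.0
OH,210,500,20000,10.0
O,100,400,3000,3.8
CO,290,770,2000,10.8
CHO,470,800,4500,22.3
COO,390,490,7000,18.0
COOH,530,420,10000,28.5
NH2,280,0,8400,19.2
NH,160,210,3100,4.5
N,20,800,5000,-9.0
NO2,500,1070,1500,24.0
S,440,0,0,12.0
S=O,440,1100,2000,15.8
ring (non-aromatic),190,0,0,16.0
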