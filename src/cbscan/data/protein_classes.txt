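# Physico-chemical bias classes for protein residue sets, derived from the
# Taylor amino-acid classification Venn diagram with additional categories.
# One class per line: LABEL RESIDUES. A region's class is the smallest listed
# class whose residue set contains all of the region's biasing residues;
# ties in size are resolved by file order; no container -> "mixed".
negative DE
glx EQ
positive HKR
aliphatic ILV
tiny AGS
tiny_polar CST
polar_aromatic HWY
aromatic FHWY
charged DEHKR
small ACDGNPSTV
polar CDEHKNQRSTWY
hydrophobic ACFGHIKLMTVWY
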