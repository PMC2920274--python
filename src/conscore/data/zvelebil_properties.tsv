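property	residues
hydrophobic	ACFGHIKLMTVWY
polar	CDEHKNQRSTWY
small	ACDGNPSTV
tiny	AGS
aliphatic	ILV
aromatic	FHWY
charged	DEHKR
positive	HKR
negative	DE
proline	P
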