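# Taylor-style stereochemical residue sets (61 sets).
# SYNTHETIC RECONSTRUCTION: generated deterministically from the Venn-diagram
# physicochemical classification (base properties, their pairwise intersections
# and pairwise/triple unions, sorted by size then membership), as a stand-in for
# the original published 61-set table, which is not reprinted anywhere machine-
# readable. Invariants preserved: the smallest set is {D,E}; the full 20-residue
# set is included; every residue is covered; set sizes lie in [2,20].
set_id	residues
T1	AG
T2	DE
T3	HK
T4	AGS
T5	HKR
T6	HWY
T7	ILV
T8	FHWY
T9	ACGTV
T10	ADEGS
T11	CDNST
T12	DEHKR
T13	DEILV
T14	AGHKRS
T15	AGILSV
T16	CHKTWY
T17	DEFHWY
T18	FHKRWY
T19	HIKLRV
T20	AFGHSWY
T21	FHILVWY
T22	ADEGHKRS
T23	ADEGILSV
T24	DEFHKRWY
T25	DEHIKLRV
T26	ACDGNPSTV
T27	ADEFGHSWY
T28	AFGHKRSWY
T29	AGHIKLRSV
T30	DEFHILVWY
T31	FHIKLRVWY
T32	ACDEGNPSTV
T33	AFGHILSVWY
T34	ACDGILNPSTV
T35	ADEFGHKRSWY
T36	ADEGHIKLRSV
T37	DEFHIKLRVWY
T38	ACDEGILNPSTV
T39	ACDGHKNPRSTV
T40	CDEHKNQRSTWY
T41	ACDEGHKNPRSTV
T42	ACDFGHNPSTVWY
T43	ACFGHIKLMTVWY
T44	CDEFHKNQRSTWY
T45	ACDEFGHNPSTVWY
T46	ACDEGHKNQRSTWY
T47	ACDGHIKLNPRSTV
T48	ACFGHIKLMRTVWY
T49	ACFGHIKLMSTVWY
T50	ACDEFGHIKLMTVWY
T51	ACDEFGHKNQRSTWY
T52	ACDEGHIKLNPRSTV
T53	ACDFGHILNPSTVWY
T54	ACDFGHKNPRSTVWY
T55	ACFGHIKLMRSTVWY
T56	CDEHIKLNQRSTVWY
T57	ACDEFGHIKLMRTVWY
T58	ACDEGHKNPQRSTVWY
T59	ACDFGHIKLMNPSTVWY
T60	ACDEFGHIKLMNQRSTVWY
T61	ACDEFGHIKLMNPQRSTVWY
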