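# CDR ranges in Kabat numbering (editable; documented literature ranges).
# Applied to author numbering only when the user asserts the structure is
# Kabat-numbered. The Chothia rows are the structural-loop definitions.
# columns: scheme domain cdr start end
kabat	L	1	24	34
kabat	L	2	50	56
kabat	L	3	89	97
kabat	H	1	31	35
kabat	H	2	50	65
kabat	H	3	95	102
chothia	L	1	26	32
chothia	L	2	50	52
chothia	L	3	91	96
chothia	H	1	26	32
chothia	H	2	52	56
chothia	H	3	96	101
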