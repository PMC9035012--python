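# NOE distance-bound corrections (nm) added to the experimental upper bound
# when a group of equivalent protons is represented by one pseudo-site or a
# wildcard.  Editable package data; the two-methyl value is the sum of two
# single-methyl corrections.
kind	correction_nm
ch2	0.10
ch3	0.10
ch3ch3	0.20
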