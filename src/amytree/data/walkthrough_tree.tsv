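haplogroup	parent	defining_markers
Root
X	Root	M100
X1	X	M110
X1a	X1	M111
Y	Root	M200
Z	Root	M300
Z1	Z	M310
Z2	Z	M320
Z2b	Z2	M322
Z2b*	Z2b
Z2b3a	Z2b	M325
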