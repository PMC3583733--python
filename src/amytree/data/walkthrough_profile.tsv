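100	G	A
200	G	A
250	C	T
300	A	C
400	G	T
450	T	A
500	A	T
600	C	A
800	T	G
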