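species	count
Cpom	26
Bmor	34
Harm	26
Dmel	29
Pxyl	25
Msex	32
Tni	28
Slit	30
Atra	23
Prap	21
Pxut	40
Dple	28
Mcin	28
Hmel	28
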