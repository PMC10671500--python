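(Dmel:320,(Pxyl:72,((Cpom:58,Atra:58):8,((Pxut:56,(Prap:48,(Dple:40,(Mcin:30,Hmel:30):10):8):8):6,((Bmor:45,Msex:45):13,(Tni:32,(Harm:24,Slit:24):8):26):4):4):6):248);
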