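# silver-behenate-like lamellar calibrant, d001 = 58.38 A
58.380000
29.190000
19.460000
14.595000
11.676000
9.730000
8.340000
7.297500
6.486667
5.838000
5.307273
4.865000
4.490769
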