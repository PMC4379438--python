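# ceria-like fluorite calibrant, a = 5.4116 A
3.124389
2.705800
1.913290
1.631659
1.562194
1.352900
1.241506
1.210071
1.104638
1.041463
0.956645
0.914727
0.901933
0.855649
0.825261
0.815829
0.781097
0.757776
0.750454
0.723155
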