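# LaB6-like cubic calibrant, a = 4.1566 A
# one d-spacing (angstrom) per line
4.156600
2.939160
2.399814
2.078300
1.858888
1.696925
1.469580
1.385533
1.314432
1.253262
1.199907
1.152833
1.110898
1.039150
1.008124
0.979720
0.953589
0.929444
0.907044
0.886190
0.848462
0.831320
0.815176
0.799938
0.771861
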