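subject,program,method,value
1,sitting,EEMD,0.09
1,sitting,MEMD,0.067
1,sitting,NA-MEMD,0
1,standing,EEMD,0.14
1,standing,MEMD,0.01
1,standing,NA-MEMD,0
1,walking,EEMD,0.03
1,walking,MEMD,0.01
1,walking,NA-MEMD,0
2,sitting,EEMD,0.09
2,sitting,MEMD,0.067
2,sitting,NA-MEMD,0
2,standing,EEMD,0.14
2,standing,MEMD,0.01
2,standing,NA-MEMD,0
2,walking,EEMD,0.05
2,walking,MEMD,0
2,walking,NA-MEMD,0.01
3,sitting,EEMD,0.12
3,sitting,MEMD,0
3,sitting,NA-MEMD,0
3,standing,EEMD,0.09
3,standing,MEMD,0.02
3,standing,NA-MEMD,0
3,walking,EEMD,0.14
3,walking,MEMD,0
3,walking,NA-MEMD,0
4,sitting,EEMD,0.09
4,sitting,MEMD,0.03
4,sitting,NA-MEMD,0.04
4,standing,EEMD,0.14
4,standing,MEMD,0.02
4,standing,NA-MEMD,0
4,walking,EEMD,0.11
4,walking,MEMD,0.04
4,walking,NA-MEMD,0
5,sitting,EEMD,0.18
5,sitting,MEMD,0.05
5,sitting,NA-MEMD,0
5,standing,EEMD,0.15
5,standing,MEMD,0.02
5,standing,NA-MEMD,0
5,walking,EEMD,0.21
5,walking,MEMD,0.03
5,walking,NA-MEMD,0.0014
6,sitting,EEMD,0.27
6,sitting,MEMD,0.06
6,sitting,NA-MEMD,0
6,standing,EEMD,0.16
6,standing,MEMD,0
6,standing,NA-MEMD,0
6,walking,EEMD,0.06
6,walking,MEMD,0
6,walking,NA-MEMD,0
7,sitting,EEMD,0.10
7,sitting,MEMD,0
7,sitting,NA-MEMD,0
7,standing,EEMD,0.08
7,standing,MEMD,0
7,standing,NA-MEMD,0
7,walking,EEMD,0.33
7,walking,MEMD,0.10
7,walking,NA-MEMD,0
8,sitting,EEMD,0.18
8,sitting,MEMD,0.01
8,sitting,NA-MEMD,0
8,standing,EEMD,0.12
8,standing,MEMD,0
8,standing,NA-MEMD,0
8,walking,EEMD,0.20
8,walking,MEMD,0.04
8,walking,NA-MEMD,0
9,sitting,EEMD,0.17
9,sitting,MEMD,0
9,sitting,NA-MEMD,0
9,standing,EEMD,0.10
9,standing,MEMD,0
9,standing,NA-MEMD,0
9,walking,EEMD,0.11
9,walking,MEMD,0
9,walking,NA-MEMD,0
10,sitting,EEMD,0.13
10,sitting,MEMD,0
10,sitting,NA-MEMD,0
10,standing,EEMD,0.24
10,standing,MEMD,0.02
10,standing,NA-MEMD,0
10,walking,EEMD,0.15
10,walking,MEMD,0.01
10,walking,NA-MEMD,0
11,sitting,EEMD,0.13
11,sitting,MEMD,0.04
11,sitting,NA-MEMD,0
11,standing,EEMD,0.08
11,standing,MEMD,0
11,standing,NA-MEMD,0
11,walking,EEMD,0.27
11,walking,MEMD,0.11
11,walking,NA-MEMD,0.02
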