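subject,program,method,value
1,sitting,EEMD,0.73
1,sitting,MEMD,0.78
1,sitting,NA-MEMD,0.84
1,standing,EEMD,0.65
1,standing,MEMD,0.74
1,standing,NA-MEMD,0.76
1,walking,EEMD,0.82
1,walking,MEMD,0.79
1,walking,NA-MEMD,0.78
2,sitting,EEMD,0.73
2,sitting,MEMD,0.78
2,sitting,NA-MEMD,0.84
2,standing,EEMD,0.65
2,standing,MEMD,0.74
2,standing,NA-MEMD,0.76
2,walking,EEMD,0.62
2,walking,MEMD,0.78
2,walking,NA-MEMD,0.79
3,sitting,EEMD,0.72
3,sitting,MEMD,0.82
3,sitting,NA-MEMD,0.88
3,standing,EEMD,0.68
3,standing,MEMD,0.80
3,standing,NA-MEMD,0.80
3,walking,EEMD,0.67
3,walking,MEMD,0.80
3,walking,NA-MEMD,0.83
4,sitting,EEMD,0.68
4,sitting,MEMD,0.78
4,sitting,NA-MEMD,0.80
4,standing,EEMD,0.77
4,standing,MEMD,0.75
4,standing,NA-MEMD,0.76
4,walking,EEMD,0.71
4,walking,MEMD,0.78
4,walking,NA-MEMD,0.76
5,sitting,EEMD,0.76
5,sitting,MEMD,0.70
5,sitting,NA-MEMD,0.76
5,standing,EEMD,0.72
5,standing,MEMD,0.80
5,standing,NA-MEMD,0.82
5,walking,EEMD,0.51
5,walking,MEMD,0.71
5,walking,NA-MEMD,0.76
6,sitting,EEMD,0.66
6,sitting,MEMD,0.64
6,sitting,NA-MEMD,0.75
6,standing,EEMD,0.80
6,standing,MEMD,0.81
6,standing,NA-MEMD,0.80
6,walking,EEMD,0.81
6,walking,MEMD,0.84
6,walking,NA-MEMD,0.81
7,sitting,EEMD,0.43
7,sitting,MEMD,0.80
7,sitting,NA-MEMD,0.77
7,standing,EEMD,0.68
7,standing,MEMD,0.88
7,standing,NA-MEMD,0.89
7,walking,EEMD,0.61
7,walking,MEMD,0.66
7,walking,NA-MEMD,0.84
8,sitting,EEMD,0.54
8,sitting,MEMD,0.82
8,sitting,NA-MEMD,0.86
8,standing,EEMD,0.69
8,standing,MEMD,0.88
8,standing,NA-MEMD,0.89
8,walking,EEMD,0.50
8,walking,MEMD,0.55
8,walking,NA-MEMD,0.79
9,sitting,EEMD,0.71
9,sitting,MEMD,0.87
9,sitting,NA-MEMD,0.87
9,standing,EEMD,0.68
9,standing,MEMD,0.90
9,standing,NA-MEMD,0.92
9,walking,EEMD,0.64
9,walking,MEMD,0.80
9,walking,NA-MEMD,0.79
10,sitting,EEMD,0.59
10,sitting,MEMD,0.90
10,sitting,NA-MEMD,0.91
10,standing,EEMD,0.60
10,standing,MEMD,0.82
10,standing,NA-MEMD,0.89
10,walking,EEMD,0.76
10,walking,MEMD,0.77
10,walking,NA-MEMD,0.79
11,sitting,EEMD,0.81
11,sitting,MEMD,0.83
11,sitting,NA-MEMD,0.86
11,standing,EEMD,0.62
11,standing,MEMD,0.86
11,standing,NA-MEMD,0.88
11,walking,EEMD,0.34
11,walking,MEMD,0.57
11,walking,NA-MEMD,0.72
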