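grade_max,interval_rp1,interval_rp2,interval_rp3,interval_max
1,44,133,233,133
1,80,164,269,80
2,30,136,216,136
2,126,231,301,126
2,105,217,329,105
2,120,218,407,120
1,36,127,304,127
2,72,184,296,72
1,112,210,,112
2,135,248,357,135
1,17,,,17
1,111,195,279,279
1,5,102,201,201
1,131,,,131
2,190,,,190
1,135,,,135
2,84,168,252,84
1,25,117,229,117
1,75,141,,75
1,50,217,302,302
2,34,,,34
2,51,161,273,51
2,119,203,315,119
1,55,149,239,149
1,43,,,43
1,35,133,231,133
1,55,,,55
1,64,161,,64
2,24,,,24
2,46,136,227,136
2,60,144,215,60
1,24,,,24
2,45,150,,45
3,27,128,212,27
2,62,178,311,62
1,17,114,224,114
2,85,268,357,85
1,55,167,293,55
1,23,,,23
2,83,181,265,83
2,124,208,293,124
2,128,240,,128
2,21,103,,103
1,112,224,315,112
1,93,177,317,93
3,48,154,287,48
2,71,147,,71
1,83,195,251,83
1,28,126,245,28
2,76,139,,76
1,25,130,,25
2,36,148,218,148
1,139,230,323,139
2,64,169,295,64
2,98,182,276,98
2,106,,,106
1,75,131,243,243
1,65,,,65
2,110,229,,110
1,98,,,98
1,41,,,41
1,17,80,,80
3,70,,,70
1,73,185,241,185
2,52,89,206,89
1,29,134,260,134
1,96,195,308,96
2,88,172,284,88
2,69,181,281,181
1,31,,,31
2,98,203,,98
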