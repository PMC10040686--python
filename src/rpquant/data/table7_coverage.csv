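grade,coverage_percent
1,99.9
1,99.4
1,99.5
1,100.0
1,99.5
1,100.0
1,100.0
1,99.6
1,89.9
1,100.0
1,86.0
1,100.0
1,58.0
1,72.8
1,98.5
1,100.0
1,99.2
1,99.8
1,96.3
1,69.8
1,77.4
1,100.0
1,99.5
1,100.0
1,95.0
1,79.6
1,87.6
1,100.0
1,98.4
1,98.2
1,59.2
1,89.8
1,98.6
1,99.9
1,0.0
1,100.0
2,100.0
2,91.8
2,89.1
2,94.7
2,96.3
2,98.9
2,97.7
2,81.0
2,52.3
2,30.9
2,100.0
2,100.0
2,80.8
2,96.7
2,93.2
2,99.8
2,85.1
2,93.7
2,95.9
2,99.1
2,79.0
2,97.5
2,86.0
2,89.7
2,31.5
2,95.7
2,63.6
2,99.5
2,100.0
2,96.3
2,78.1
2,91.6
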