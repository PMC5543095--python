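block,mean_pct,sd_pct
1,64.3,13.5
2,77.0,16.4
3,81.6,15.9
4,85.7,13.7
5,90.5,10.7
6,90.4,12.2
7,56.5,17.7
8,81.0,18.5
9,83.4,18.9
10,86.4,15.6
11,90.0,14.4
12,89.7,13.9
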