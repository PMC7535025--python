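item,frequency,category
1,1,1
1,2,2
1,3,2
2,1,2
2,2,2
2,3,2
3,1,2
3,2,3
3,3,3
4,1,2
4,2,3
4,3,3
5,1,3
5,2,3
5,3,4
6,1,3
6,2,3
6,3,4
7,1,4
7,2,4
7,3,4
8,1,4
8,2,4
8,3,4
9,1,4
9,2,4
9,3,4
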