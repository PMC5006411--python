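center,arm,events,total
1,active,11,36
1,control,10,37
2,active,16,20
2,control,22,32
3,active,14,19
3,control,7,19
4,active,2,16
4,control,1,17
5,active,6,17
5,control,0,12
6,active,1,11
6,control,0,10
7,active,1,5
7,control,1,9
8,active,4,6
8,control,6,7
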