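bin_left,bin_right,density
0.5,1.5,0.0
1.5,2.5,0.0
2.5,3.5,0.0
3.5,4.5,1.0
4.5,5.5,0.0
5.5,6.5,0.0
6.5,7.5,0.0
7.5,8.5,0.0
8.5,9.5,0.0
9.5,10.5,0.0
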