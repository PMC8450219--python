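bin_left,bin_right,density
-1.0,-0.9,0.9277996438800233
-0.9,-0.8,0.8990213445424451
-0.8,-0.7,0.8455578265296029
-0.7,-0.6,0.7746404313562693
-0.6,-0.5,0.6950360422928104
-0.5,-0.4,0.6152854400628257
-0.4,-0.3,0.5422651576135562
-0.3,-0.2,0.48038380212473963
-0.2,-0.1,0.43147777601685655
-0.1,-0.0,0.3952562754176464
-0.0,0.1,0.3700321440356311
0.1,0.2,0.3534766652570802
0.2,0.3,0.34321770201526297
0.3,0.4,0.33720764164240324
0.4,0.5,0.3338755526002779
0.5,0.6,0.3321258169226477
0.6,0.7,0.33125498760449407
0.7,0.8,0.33084399616245336
0.8,0.9,0.33065997585558937
0.9,1.0,0.33058177806738537
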