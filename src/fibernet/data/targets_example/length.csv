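bin_left,bin_right,density
0.0,0.5,1.4742641260928375e-13
0.5,1.0,9.973017799046282e-07
1.0,1.5,0.00016090966117126608
1.5,2.0,0.002113865177633119
2.0,2.5,0.009694880490853937
2.5,3.0,0.025580341708901645
3.0,3.5,0.048567385815770144
3.5,4.0,0.07457517465625756
4.0,4.5,0.09907370940749315
4.5,5.0,0.11874740275779247
5.0,5.5,0.1319791927498702
5.5,6.0,0.1385934846475007
6.0,6.5,0.13934419227727493
6.5,7.0,0.1354324999031266
7.0,7.5,0.1281597757361225
7.5,8.0,0.11872178421028116
8.0,8.5,0.1081120188897168
8.5,9.0,0.09709605048346176
9.0,9.5,0.08622569800906862
9.5,10.0,0.07587151473472971
10.0,10.5,0.0662604668546646
10.5,11.0,0.057511722797494155
11.0,11.5,0.04966735211998679
11.5,12.0,0.042716999889847326
12.0,12.5,0.0366167929124998
12.5,13.0,0.03130326453879836
13.0,13.5,0.026703241251424203
13.5,14.0,0.02274059829104891
14.0,14.5,0.01934067098008163
14.5,15.0,0.016432962809207696
15.0,15.5,0.013952650996353849
15.5,16.0,0.01184126826501198
16.0,16.5,0.01004683987730001
16.5,17.0,0.008523676704913592
17.0,17.5,0.007231965532970599
17.5,18.0,0.006137253491596218
18.0,18.5,0.005209891245169587
18.5,19.0,0.004424476510403448
19.0,19.5,0.0037593233022574254
19.5,20.0,0.0031959711913574105
20.0,20.5,0.002718741394125386
20.5,21.0,0.0023143416524419084
21.0,21.5,0.001971518814386745
21.5,22.0,0.0016807562345298721
22.0,22.5,0.0014340121642852212
22.5,23.0,0.0012244949114214095
23.0,23.5,0.0010464705110843158
23.5,24.0,0.0008950988294557916
24.0,24.5,0.0007662943211057946
24.5,25.0,0.0006566080195508914
25.0,25.5,0.0005631277170369442
25.5,26.0,0.00048339365895294786
26.0,26.5,0.00041532742580938005
26.5,27.0,0.0003571719935949041
27.0,27.5,0.00030744124832671123
27.5,28.0,0.0002648774823781092
28.0,28.5,0.00022841562008663714
28.5,29.0,0.00019715311057348254
29.0,29.5,0.00017032458946249443
29.5,30.0,0.00014728055123871728
30.0,30.5,0.0001274693932370403
30.5,31.0,0.00011042229343084003
31.0,31.5,9.574046979129269e-05
31.5,32.0,8.308444124209892e-05
32.0,32.5,7.216497110996121e-05
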