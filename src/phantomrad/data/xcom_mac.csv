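element,energy_keV,mac_cm2_per_g
H,5,0.4193
H,6,0.4042
H,8,0.3914
H,10,0.3854
H,12,0.381327
H,15,0.3764
H,18,0.372012
H,20,0.3695
H,25,0.362568
H,30,0.357
H,35,0.350954
H,40,0.3458
H,45,0.340324
H,50,0.3355
H,55,0.3305
H,60,0.326
H,70,0.316833
H,80,0.3091
H,90,0.301252
H,100,0.2944
H,110,0.287234
H,120,0.280844
H,130,0.275092
H,140,0.269871
H,150,0.2651
H,175,0.252963
H,200,0.2429
C,5,18.9
C,6,10.6
C,8,4.51
C,10,2.373
C,12,1.46113
C,15,0.8071
C,18,0.551056
C,20,0.442
C,25,0.3274
C,30,0.2562
C,35,0.228891
C,40,0.2076
C,45,0.196514
C,50,0.1871
C,55,0.180836
C,60,0.1753
C,70,0.167486
C,80,0.161
C,90,0.155859
C,100,0.1514
C,110,0.147297
C,120,0.143649
C,130,0.140372
C,140,0.137406
C,150,0.1347
C,175,0.128243
C,200,0.1229
N,5,31
N,6,17.7
N,8,7.47
N,10,3.879
N,12,2.31939
N,15,1.236
N,18,0.796432
N,20,0.6178
N,25,0.420139
N,30,0.3066
N,35,0.262095
N,40,0.2288
N,45,0.211989
N,50,0.198
N,55,0.189304
N,60,0.1817
N,70,0.171934
N,80,0.1639
N,90,0.157999
N,100,0.1529
N,110,0.148567
N,120,0.144719
N,130,0.141267
N,140,0.138145
N,150,0.1353
N,175,0.128732
N,200,0.1233
O,5,47.5
O,6,27.6
O,8,11.6
O,10,5.952
O,12,3.50736
O,15,1.836
O,18,1.13961
O,20,0.8651
O,25,0.548422
O,30,0.3779
O,35,0.308325
O,40,0.2585
O,45,0.233504
O,50,0.2132
O,55,0.201125
O,60,0.1907
O,70,0.178066
O,80,0.1678
O,90,0.160972
O,100,0.1551
O,110,0.150408
O,120,0.146249
O,130,0.142524
O,140,0.13916
O,150,0.1361
O,175,0.129309
O,200,0.1237
Al,5,193.4
Al,6,115.3
Al,8,50.33
Al,10,26.23
Al,12,15.3392
Al,15,7.955
Al,18,4.67799
Al,20,3.442
Al,25,1.86282
Al,30,1.128
Al,35,0.781368
Al,40,0.5685
Al,45,0.451954
Al,50,0.3681
Al,55,0.317737
Al,60,0.2778
Al,70,0.234073
Al,80,0.2018
Al,90,0.184566
Al,100,0.1704
Al,110,0.162103
Al,120,0.154882
Al,130,0.148524
Al,140,0.14287
Al,150,0.1378
Al,175,0.129265
Al,200,0.1223
Si,5,245
Si,6,147
Si,8,64.68
Si,10,33.89
Si,12,19.8723
Si,15,10.34
Si,18,6.07193
Si,20,4.464
Si,25,2.39135
Si,30,1.436
Si,35,0.978006
Si,40,0.7012
Si,45,0.547307
Si,50,0.4385
Si,55,0.372342
Si,60,0.3207
Si,70,0.263839
Si,80,0.2228
Si,90,0.201108
Si,100,0.1835
Si,110,0.173562
Si,120,0.164961
Si,130,0.157425
Si,140,0.150755
Si,150,0.1448
Si,175,0.135257
Si,200,0.1275
Na,5,129.586
Na,6,74.2551
Na,8,30.8982
Na,10,15.7
Na,12,9.06432
Na,15,4.66783
Na,18,2.74741
Na,20,2.03848
Na,25,1.11466
Na,30,0.710124
Na,35,0.50491
Na,40,0.389841
Na,45,0.319699
Na,50,0.2745
Na,55,0.243582
Na,60,0.221734
Na,70,0.193055
Na,80,0.175826
Na,90,0.163947
Na,100,0.155502
Na,110,0.148627
Na,120,0.143186
Na,130,0.138732
Na,140,0.134985
Na,150,0.131766
Na,175,0.124443
Na,200,0.118771
Mg,5,172.075
Mg,6,98.579
Mg,8,40.9877
Mg,10,20.8
Mg,12,11.9861
Mg,15,6.1467
Mg,18,3.59633
Mg,20,2.65498
Mg,25,1.42881
Mg,30,0.892247
Mg,35,0.620514
Mg,40,0.468399
Mg,45,0.376009
Mg,50,0.31666
Mg,55,0.276304
Mg,60,0.247926
Mg,70,0.211141
Mg,80,0.189361
Mg,90,0.174703
Mg,100,0.164465
Mg,110,0.156358
Mg,120,0.150043
Mg,130,0.144949
Mg,140,0.140719
Mg,150,0.137124
Mg,175,0.129132
Mg,200,0.123038
P,5,333.059
P,6,190.725
P,8,79.1946
P,10,40.1
P,12,23.032
P,15,11.7253
P,18,6.78805
P,20,4.96613
P,25,2.59471
P,30,1.55819
P,35,1.0348
P,40,0.742654
P,45,0.566326
P,50,0.45368
P,55,0.377902
P,60,0.325082
P,70,0.258202
P,80,0.219698
P,90,0.195044
P,100,0.178475
P,110,0.166183
P,120,0.156993
P,130,0.149863
P,140,0.144154
P,150,0.139462
P,175,0.129757
P,200,0.122741
S,5,418.082
S,6,239.396
S,8,99.3795
S,10,50.3
S,12,28.873
S,15,14.6788
S,18,8.48101
S,20,6.19401
S,25,3.21764
S,30,1.91699
S,35,1.26058
S,40,0.894379
S,45,0.673615
S,50,0.532726
S,55,0.438142
S,60,0.372325
S,70,0.289369
S,80,0.241879
S,90,0.21179
S,100,0.191741
S,110,0.177096
S,120,0.166261
S,130,0.15794
S,140,0.151347
S,150,0.14598
S,175,0.135129
S,200,0.127425
Cl,5,482.353
Cl,6,276.182
Cl,8,114.629
Cl,10,58
Cl,12,33.2773
Cl,15,16.9002
Cl,18,9.74949
Cl,20,7.11094
Cl,25,3.67741
Cl,30,2.17722
Cl,35,1.42043
Cl,40,0.998396
Cl,45,0.744204
Cl,50,0.582111
Cl,55,0.473463
Cl,60,0.397958
Cl,70,0.303131
Cl,80,0.249087
Cl,90,0.215131
Cl,100,0.192662
Cl,110,0.17646
Cl,120,0.164579
Cl,130,0.155537
Cl,140,0.148435
Cl,150,0.142706
Cl,175,0.131364
Cl,200,0.123452
K,5,657.469
K,6,376.421
K,8,156.195
K,10,79
K,12,45.2989
K,15,22.9746
K,18,13.2275
K,20,9.63109
K,25,4.9517
K,30,2.90761
K,35,1.87697
K,40,1.30253
K,45,0.956943
K,50,0.736795
K,55,0.589533
K,60,0.487365
K,70,0.359648
K,80,0.287283
K,90,0.242322
K,100,0.212851
K,110,0.191977
K,120,0.17686
K,130,0.165507
K,140,0.15671
K,150,0.149707
K,175,0.136297
K,200,0.127213
Ca,5,777.525
Ca,6,445.144
Ca,8,184.694
Ca,10,93.4
Ca,12,53.5437
Ca,15,27.1422
Ca,18,15.6152
Ca,20,11.362
Ca,25,5.82847
Ca,30,3.41144
Ca,35,2.19303
Ca,40,1.51406
Ca,45,1.10576
Ca,50,0.845775
Ca,55,0.671996
Ca,60,0.551511
Ca,70,0.401166
Ca,80,0.316173
Ca,90,0.263598
Ca,100,0.229268
Ca,110,0.205127
Ca,120,0.187738
Ca,130,0.174749
Ca,140,0.164743
Ca,150,0.156825
Ca,175,0.141892
Ca,200,0.131917
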