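30.273081
29.508062
28.743043
27.978024
27.213005
26.447985
25.682966
24.917947
24.152928
23.387909
22.622890
23.483283
24.343675
25.204068
26.064461
26.924854
27.785247
28.645639
29.506032
30.366425
31.226818
30.373029
29.519241
28.665452
27.811664
26.957875
26.104087
25.250298
24.396510
23.542721
22.688933
23.542339
24.395744
25.249150
26.102556
26.955962
27.809368
28.662773
29.516179
30.369585
31.222991
30.369586
29.516180
28.662775
27.809370
26.955965
26.102560
25.249154
24.395749
23.542344
22.688939
23.542343
24.395747
25.249152
26.102556
26.955961
27.809365
28.662769
29.516174
30.369578
31.222983
30.369578
29.516174
28.662769
27.809365
26.955961
26.102556
25.249152
24.395747
23.542343
22.688939
23.542343
24.395747
25.249152
26.102556
26.955961
27.809365
28.662769
29.516174
30.369578
31.222983
30.369578
29.516174
28.662769
27.809365
26.955961
26.102556
25.249152
24.395747
23.542343
22.688939
23.542343
24.395748
25.249153
26.102557
26.955962
27.809366
28.662771
29.516176
30.369580
31.222985
30.369587
29.516189
28.662791
27.809394
26.955996
26.102598
25.249200
24.395802
23.542404
22.689006
23.542483
24.395959
25.249435
26.102911
26.956387
27.809863
28.663339
29.516815
30.370291
31.223767
30.373696
29.523625
28.673553
27.823482
26.973411
26.123340
25.273269
24.423198
23.573127
22.723055
23.406963
24.090871
24.774778
25.458686
26.142593
26.826501
27.510408
28.194316
28.878223
29.562131
27.747466
25.932801
24.118136
22.303471
20.488807
18.674142
16.859477
15.044812
13.230147
11.415482
11.794665
12.173848
12.553032
12.932215
13.311398
13.690581
14.069765
14.448948
14.828131
15.207314
15.772592
16.337870
16.903147
17.468425
18.033703
18.598981
19.164258
19.729536
20.294814
20.860092
21.421977
21.983862
22.545747
23.107633
23.669518
24.231403
24.793288
25.355173
25.917059
26.478944
27.099718
27.720492
28.341266
28.962040
29.582814
30.203587
30.824361
31.445135
32.065909
32.686683
33.338477
33.990271
34.642065
35.293859
35.945653
36.597447
37.249241
37.901035
38.552829
39.204623
39.813921
40.423220
41.032518
41.641817
42.251115
42.860414
43.469712
44.079011
44.688309
45.297607
45.811131
46.324654
46.838178
47.351701
47.865224
48.378748
48.892271
49.405795
49.919318
50.432841
50.829739
51.226637
51.623535
52.020433
52.417331
52.814228
53.211126
53.608024
54.004922
54.401820
54.682996
54.964173
55.245349
55.526526
55.807703
56.088879
56.370056
56.651233
56.932409
57.213586
57.386345
57.559104
57.731863
57.904622
58.077381
58.250139
58.422898
58.595657
58.768416
58.941175
59.005266
59.069356
59.133447
59.197538
59.261628
59.325719
59.389809
59.453900
59.517991
59.582081
59.517421
59.452761
59.388101
59.323440
59.258780
59.194120
59.129459
59.064799
59.000139
58.935479
58.689283
58.443087
58.196890
57.950694
57.704498
57.458302
57.212106
56.965910
56.719714
56.473518
55.943545
55.413572
54.883600
54.353627
53.823654
53.293682
52.763709
52.233736
51.703763
51.173791
50.188576
49.203361
48.218145
47.232930
46.247715
45.262500
44.277285
43.292070
42.306855
41.321640
39.657904
37.994168
36.330432
34.666695
33.002959
31.339223
29.675487
28.011751
26.348015
24.684278
22.378824
20.073370
17.767915
15.462461
13.157007
10.851552
8.546098
6.240644
3.935190
1.629735
1.566762
1.503788
1.440815
1.377841
1.314868
1.251894
1.188921
1.125947
1.062974
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.000000
1.303501
1.607003
1.910504
2.214005
2.517507
2.821008
3.124510
3.428011
3.731512
4.035014
9.035014
14.035014
19.035014
24.035014
29.035014
34.035014
39.035014
44.035014
49.035014
54.035014
50.405005
46.774996
43.144987
39.514978
35.884969
32.254960
28.624952
24.994943
21.364934
17.734925
17.655474
17.576023
17.496572
17.417121
17.337670
17.258219
17.178768
17.099317
17.019866
16.940415
16.853466
16.766516
16.679567
16.592618
16.505668
16.418719
16.331770
16.244820
16.157871
16.070922
15.736877
15.402831
15.068786
14.734741
14.400696
14.066650
13.732605
13.398560
13.064515
12.730469
12.508901
12.287333
12.065765
11.844197
11.622629
11.401061
11.179493
10.957925
10.736357
10.514789
10.540445
10.566102
10.591758
10.617415
10.643071
10.668728
10.694384
10.720041
10.745697
10.771354
11.015132
11.258910
11.502688
11.746466
11.990244
12.234022
12.477801
12.721579
12.965357
13.209135
13.591446
13.973758
14.356069
14.738380
15.120692
15.503003
15.885314
16.267626
16.649937
17.032249
17.469009
17.905769
18.342529
18.779289
19.216049
19.652810
20.089570
20.526330
20.963090
21.399850
21.823884
22.247918
22.671952
23.095986
23.520020
23.944053
24.368087
24.792121
25.216155
25.640189
26.009849
26.379509
26.749169
27.118830
27.488490
27.858150
28.227810
28.597471
28.967131
29.336791
29.634753
29.932714
30.230676
30.528638
30.826600
31.124561
31.422523
31.720485
32.018446
32.316408
32.543023
32.769637
32.996251
33.222866
33.449480
33.676095
33.902709
34.129323
34.355938
34.582552
34.748156
34.913759
35.079363
35.244966
35.410570
35.576173
35.741777
35.907380
36.072984
36.238587
36.357396
36.476205
36.595014
36.713823
36.832632
36.951441
37.070250
37.189059
37.307867
37.426676
37.513029
37.599381
37.685733
37.772086
37.858438
37.944790
38.031142
38.117495
38.203847
38.290199
38.356824
38.423449
38.490074
38.556699
38.623324
38.689949
38.756574
38.823199
38.889824
38.956449
39.014065
39.071680
39.129295
39.186910
39.244526
39.302141
39.359756
39.417371
39.474987
39.532602
39.590163
39.647725
39.705286
39.762847
39.820409
39.877970
39.935531
39.993093
40.050654
40.108215
40.173356
40.238497
40.303638
40.368779
40.433920
40.499061
40.564202
40.629343
40.694484
40.759625
40.838919
40.918213
40.997507
41.076801
41.156095
41.235389
41.314683
41.393977
41.473271
41.552565
41.651324
41.750083
41.848841
41.947600
42.046359
42.145118
42.243877
42.342636
42.441395
42.540153
42.661201
42.782248
42.903296
43.024343
43.145390
43.266438
43.387485
43.508533
43.629580
43.750627
43.891558
44.032488
44.173418
44.314348
44.455278
44.596208
44.737138
44.878068
45.018998
45.159928
45.307633
45.455338
45.603042
45.750747
45.898452
46.046157
46.193862
46.341567
46.489271
46.636976
46.751873
46.866769
46.981666
47.096562
47.211459
47.326355
47.441252
47.556148
47.671045
47.785941
47.698664
47.611386
47.524108
47.436831
47.349553
47.262276
47.174998
47.087721
47.000443
46.913166
45.993805
45.074445
44.155085
43.235724
42.316364
41.397004
40.477643
39.558283
38.638923
37.719563
35.840698
33.961834
32.082970
30.204106
28.325242
26.446377
24.567513
22.688649
20.809785
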