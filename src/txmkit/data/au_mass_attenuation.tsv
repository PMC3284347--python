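# Gold (Z=79) total mass attenuation coefficient, tabulated
# energy_eV	mu_rho_cm2_g
6000	425.166
6010	423.395
6020	421.634
6030	419.883
6040	418.142
6050	416.412
6060	414.692
6070	412.981
6080	411.281
6090	409.59
6100	407.909
6110	406.238
6120	404.577
6130	402.925
6140	401.282
6150	399.649
6160	398.025
6170	396.411
6180	394.805
6190	393.209
6200	391.622
6210	390.044
6220	388.475
6230	386.915
6240	385.363
6250	383.82
6260	382.286
6270	380.761
6280	379.244
6290	377.736
6300	376.236
6310	374.744
6320	373.261
6330	371.786
6340	370.319
6350	368.861
6360	367.41
6370	365.967
6380	364.533
6390	363.106
6400	361.687
6410	360.276
6420	358.873
6430	357.477
6440	356.089
6450	354.709
6460	353.336
6470	351.971
6480	350.613
6490	349.262
6500	347.919
6510	346.583
6520	345.254
6530	343.932
6540	342.618
6550	341.31
6560	340.01
6570	338.716
6580	337.43
6590	336.15
6600	334.877
6610	333.611
6620	332.352
6630	331.099
6640	329.853
6650	328.614
6660	327.381
6670	326.155
6680	324.935
6690	323.721
6700	322.514
6710	321.313
6720	320.119
6730	318.931
6740	317.749
6750	316.573
6760	315.403
6770	314.24
6780	313.082
6790	311.93
6800	310.785
6810	309.645
6820	308.511
6830	307.383
6840	306.261
6850	305.145
6860	304.034
6870	302.929
6880	301.83
6890	300.736
6900	299.648
6910	298.565
6920	297.488
6930	296.417
6940	295.35
6950	294.29
6960	293.234
6970	292.184
6980	291.139
6990	290.1
7000	289.066
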