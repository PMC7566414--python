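subject	x_displacement_mm	y_displacement_mm	z_displacement_mm
1	0.0028	0.0102	0.005
2	0.0059	0.011	0.0039
3	0.0096	0.0121	0.0114
4	0.0161	0.0866	0.0024
5	0.0026	0.0369	0.004
6	0.0036	0.0392	0.0066
7	0.0066	0.0458	0.0071
8	0.0037	0.0448	0.0108
9	0.0057	0.0465	0.0187
10	0.0158	0.0376	0.0303
11	0.0184	0.059	0.0413
12	0.0018	0.0494	0.0392
13	0.0032	0.0542	0.0414
14	0.071	0.041	0.0342
15	0.0374	0.1123	0.0422
16	0.0449	0.1163	0.0566
17	0.0506	0.1351	0.0417
18	0.0873	0.1532	0.0321
19	0.1021	0.1101	0.0584
20	0.0737	0.1371	0.0537
21	0.0621	0.1464	0.0484
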