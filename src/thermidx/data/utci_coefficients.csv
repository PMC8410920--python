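i_ta,j_va,k_dmrt,l_pa,coefficient
0,0,0,0,0.607562052
1,0,0,0,-0.0227712343
2,0,0,0,0.000806470249
3,0,0,0,-0.000154271372
4,0,0,0,-3.24651735e-06
5,0,0,0,7.32602852e-08
6,0,0,0,1.35959073e-09
0,1,0,0,-2.2583652
1,1,0,0,0.0880326035
2,1,0,0,0.00216844454
3,1,0,0,-1.53347087e-05
4,1,0,0,-5.72983704e-07
5,1,0,0,-2.55090145e-09
0,2,0,0,-0.751269505
1,2,0,0,-0.00408350271
2,2,0,0,-5.21670675e-05
3,2,0,0,1.94544667e-06
4,2,0,0,1.14099531e-08
0,3,0,0,0.158137256
1,3,0,0,-6.57263143e-05
2,3,0,0,2.22697524e-07
3,3,0,0,-4.16117031e-08
0,4,0,0,-0.0127762753
1,4,0,0,9.66891875e-06
2,4,0,0,2.52785852e-09
0,5,0,0,0.000456306672
1,5,0,0,-1.74202546e-07
0,6,0,0,-5.91491269e-06
0,0,1,0,0.398374029
1,0,1,0,0.000183945314
2,0,1,0,-0.00017375451
3,0,1,0,-7.60781159e-07
4,0,1,0,3.77830287e-08
5,0,1,0,5.43079673e-10
0,1,1,0,-0.0200518269
1,1,1,0,0.000892859837
2,1,1,0,3.45433048e-06
3,1,1,0,-3.77925774e-07
4,1,1,0,-1.69699377e-09
0,2,1,0,0.000169992415
1,2,1,0,-4.99204314e-05
2,2,1,0,2.47417178e-07
3,2,1,0,1.07596466e-08
0,3,1,0,8.49242932e-05
1,3,1,0,1.35191328e-06
2,3,1,0,-6.21531254e-09
0,4,1,0,-4.99410301e-06
1,4,1,0,-1.89489258e-08
0,5,1,0,8.15300114e-08
0,0,2,0,0.00075504309
1,0,2,0,-5.65095215e-05
2,0,2,0,-4.52166564e-07
3,0,2,0,2.46688878e-08
4,0,2,0,2.42674348e-10
0,1,2,0,0.00015454725
1,1,2,0,5.2411097e-06
2,1,2,0,-8.75874982e-08
3,1,2,0,-1.50743064e-09
0,2,2,0,-1.56236307e-05
1,2,2,0,-1.33895614e-07
2,2,2,0,2.49709824e-09
0,3,2,0,6.51711721e-07
1,3,2,0,1.94960053e-09
0,4,2,0,-1.00361113e-08
0,0,3,0,-1.21206673e-05
1,0,3,0,-2.1820366e-07
2,0,3,0,7.51269482e-09
3,0,3,0,9.79063848e-11
0,1,3,0,1.25006734e-06
1,1,3,0,-1.81584736e-09
2,1,3,0,-3.52197671e-10
0,2,3,0,-3.3651463e-08
1,2,3,0,1.35908359e-10
0,3,3,0,4.1703262e-10
0,0,4,0,-1.30369025e-09
1,0,4,0,4.13908461e-10
2,0,4,0,9.22652254e-12
0,1,4,0,-5.08220384e-09
1,1,4,0,-2.24730961e-11
0,2,4,0,1.17139133e-10
0,0,5,0,6.62154879e-10
1,0,5,0,4.0386326e-13
0,1,5,0,1.95087203e-12
0,0,6,0,-4.73602469e-12
0,0,0,1,5.12733497
1,0,0,1,-0.312788561
2,0,0,1,-0.0196701861
3,0,0,1,0.00099969087
4,0,0,1,9.51738512e-06
5,0,0,1,-4.66426341e-07
0,1,0,1,0.548050612
1,1,0,1,-0.00330552823
2,1,0,1,-0.0016411944
3,1,0,1,-5.16670694e-06
4,1,0,1,9.52692432e-07
0,2,0,1,-0.0429223622
1,2,0,1,0.00500845667
2,2,0,1,1.00601257e-06
3,2,0,1,-1.81748644e-06
0,3,0,1,-0.00125813502
1,3,0,1,-0.000179330391
2,3,0,1,2.34994441e-06
0,4,0,1,0.000129735808
1,4,0,1,1.2906487e-06
0,5,0,1,-2.28558686e-06
0,0,1,1,-0.0369476348
1,0,1,1,0.00162325322
2,0,1,1,-3.1427968e-05
3,0,1,1,2.59835559e-06
4,0,1,1,-4.77136523e-08
0,1,1,1,0.0086420339
1,1,1,1,-0.000687405181
2,1,1,1,-9.13863872e-06
3,1,1,1,5.15916806e-07
0,2,1,1,-3.59217476e-05
1,2,1,1,3.28696511e-05
2,2,1,1,-7.10542454e-07
0,3,1,1,-1.243823e-05
1,3,1,1,-7.385844e-09
0,4,1,1,2.20609296e-07
0,0,2,1,-0.00073246918
1,0,2,1,-1.87381964e-05
2,0,2,1,4.80925239e-06
3,0,2,1,-8.7549204e-08
0,1,2,1,2.7786293e-05
1,1,2,1,-5.06004592e-06
2,1,2,1,1.14325367e-07
0,2,2,1,2.53016723e-06
1,2,2,1,-1.72857035e-08
0,3,2,1,-3.95079398e-08
0,0,3,1,-3.59413173e-07
1,0,3,1,7.04388046e-07
2,0,3,1,-1.89309167e-08
0,1,3,1,-4.79768731e-07
1,1,3,1,7.96079978e-09
0,2,3,1,1.62897058e-09
0,0,4,1,3.94367674e-08
1,0,4,1,-1.18566247e-09
0,1,4,1,3.34678041e-10
0,0,5,1,-1.15606447e-10
0,0,0,2,-2.80626406
1,0,0,2,0.548712484
2,0,0,2,-0.0039942841
3,0,0,2,-0.000954009191
4,0,0,2,1.93090978e-05
0,1,0,2,-0.308806365
1,1,0,2,0.0116952364
2,1,0,2,0.000495271903
3,1,0,2,-1.90710882e-05
0,2,0,2,0.00210787756
1,2,0,2,-0.000698445738
2,2,0,2,2.30109073e-05
0,3,0,2,0.00041785659
1,3,0,2,-1.27043871e-05
0,4,0,2,-3.04620472e-06
0,0,1,2,0.0514507424
1,0,1,2,-0.00432510997
2,0,1,2,8.99281156e-05
3,0,1,2,-7.14663943e-07
0,1,1,2,-0.000266016305
1,1,1,2,0.000263789586
2,1,1,2,-7.01199003e-06
0,2,1,2,-0.000106823306
1,2,1,2,3.61341136e-06
0,3,1,2,2.29748967e-07
0,0,2,2,0.000304788893
1,0,2,2,-6.42070836e-05
2,0,2,2,1.16257971e-06
0,1,2,2,7.68023384e-06
1,1,2,2,-5.47446896e-07
0,2,2,2,-3.5993791e-08
0,0,3,2,-4.36497725e-06
1,0,3,2,1.68737969e-07
0,1,3,2,2.67489271e-08
0,0,4,2,3.23926897e-09
0,0,0,3,-0.0353874123
1,0,0,3,-0.22120119
2,0,0,3,0.0155126038
3,0,0,3,-0.000263917279
0,1,0,3,0.0453433455
1,1,0,3,-0.00432943862
2,1,0,3,0.000145389826
0,2,0,3,0.00021750861
1,2,0,3,-6.66724702e-05
0,3,0,3,3.3321714e-05
0,0,1,3,-0.00226921615
1,0,1,3,0.000380261982
2,0,1,3,-5.45314314e-09
0,1,1,3,-0.000796355448
1,1,1,3,2.53458034e-05
0,2,1,3,-6.31223658e-06
0,0,2,3,0.000302122035
1,0,2,3,-4.77403547e-06
0,1,2,3,1.73825715e-06
0,0,3,3,-4.09087898e-07
0,0,0,4,0.614155345
1,0,0,4,-0.0616755931
2,0,0,4,0.00133374846
0,1,0,4,0.00355375387
1,1,0,4,-0.000513027851
0,2,0,4,0.000102449757
0,0,1,4,-0.00148526421
1,0,1,4,-4.11469183e-05
0,1,1,4,-6.80434415e-06
0,0,2,4,-9.77675906e-06
0,0,0,5,0.0882773108
1,0,0,5,-0.00301859306
0,1,0,5,0.00104452989
0,0,1,5,0.000247090539
0,0,0,6,0.00148348065
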