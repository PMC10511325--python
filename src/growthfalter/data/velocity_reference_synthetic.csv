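sex,interval,percentile,cm_per_month
male,0-3,p1,1.7633
male,0-3,p15,2.5633
male,0-3,p25,2.8567
male,0-3,p50,3.23
male,0-3,p75,3.6033
male,3-6,p1,1.1133
male,3-6,p15,1.6133
male,3-6,p25,1.7967
male,3-6,p50,2.03
male,3-6,p75,2.2633
male,6-9,p1,0.8154
male,6-9,p15,1.1779
male,6-9,p25,1.3108
male,6-9,p50,1.48
male,6-9,p75,1.6492
male,9-12,p1,0.68
male,9-12,p15,0.98
male,9-12,p25,1.09
male,9-12,p50,1.23
male,9-12,p75,1.37
male,12-15,p1,0.5987
male,12-15,p15,0.8613
male,12-15,p25,0.9575
male,12-15,p50,1.08
male,12-15,p75,1.2025
male,15-18,p1,0.5446
male,15-18,p15,0.7821
male,15-18,p25,0.8692
male,15-18,p50,0.98
male,15-18,p75,1.0908
male,18-21,p1,0.5067
male,18-21,p15,0.7267
male,18-21,p25,0.8073
male,18-21,p50,0.91
male,18-21,p75,1.0127
male,21-24,p1,0.4742
male,21-24,p15,0.6792
male,21-24,p25,0.7543
male,21-24,p50,0.85
male,21-24,p75,0.9457
female,0-3,p1,1.7033
female,0-3,p15,2.5033
female,0-3,p25,2.7967
female,0-3,p50,3.17
female,0-3,p75,3.5433
female,3-6,p1,1.0533
female,3-6,p15,1.5533
female,3-6,p25,1.7367
female,3-6,p50,1.97
female,3-6,p75,2.2033
female,6-9,p1,0.7554
female,6-9,p15,1.1179
female,6-9,p25,1.2508
female,6-9,p50,1.42
female,6-9,p75,1.5892
female,9-12,p1,0.62
female,9-12,p15,0.92
female,9-12,p25,1.03
female,9-12,p50,1.17
female,9-12,p75,1.31
female,12-15,p1,0.5387
female,12-15,p15,0.8013
female,12-15,p25,0.8975
female,12-15,p50,1.02
female,12-15,p75,1.1425
female,15-18,p1,0.4846
female,15-18,p15,0.7221
female,15-18,p25,0.8092
female,15-18,p50,0.92
female,15-18,p75,1.0308
female,18-21,p1,0.4467
female,18-21,p15,0.6667
female,18-21,p25,0.7473
female,18-21,p50,0.85
female,18-21,p75,0.9527
female,21-24,p1,0.4142
female,21-24,p15,0.6192
female,21-24,p25,0.6943
female,21-24,p50,0.79
female,21-24,p75,0.8857
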