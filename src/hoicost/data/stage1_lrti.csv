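year,term,estimate,se,ci_low,ci_high
2011,intercept,-4180.48,91.1787,-4359.192,-4001.767
2011,los,1324.030,12.2049,1300.1083,1347.9519
2011,ndx,89.3800,5.9700,77.6787,101.0814
2011,npr,1916.808,41.1644,1836.1245,1997.4906
2011,urban_teaching,272.0654,22.1886,228.5752,315.5556
2011,small_bedsize,-551.727,33.9330,-618.2360,-485.2170
2011,age,2.3119,0.5740,1.1868,3.4370
2011,severity,150.6755,27.3487,97.0713,204.2796
2011,risk_mortality,103.7112,39.6886,25.9206,181.5019
2011,wage_index,4016.947,78.7623,3862.5711,4171.3228
2016,intercept,-4428.3,92.3444,-4609.313,-4247.32
2016,los,1476.475,10.8909,1455.129,1497.8214
2016,ndx,66.0973,4.87,56.552,75.6426
2016,npr,1322.245,25.6503,1271.97,1372.5205
2016,urban_teaching,334.9984,28.5321,279.075,390.9218
2016,small_bedsize,-649.742,37.0221,-722.3062,-577.1779
2016,age,-2.2123,0.6268,-3.4408,-0.9838
2016,severity,447.6694,26.6918,395.3529,499.9858
2016,risk_mortality,-145.316,29.054,-202.2622,-88.3695
2016,wage_index,4347.944,71.203,4208.385,4487.5038
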