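year,group,n,cost_mean,cost_median,los_mean,ndx_mean,npr_mean,age_mean,severity_mean,risk_mortality_mean,wage_index_mean
2011,secondary,31266,26839,11335,10.35,13.10,2.30,54,2.86,2.34,0.9900
2011,principal,40735,7415,3833,3.83,6.26,0.55,27,1.89,1.40,0.9871
2011,no_infection,156330,13671,7784,5.63,11.05,1.43,59,2.49,2.12,0.9969
2016,secondary,167961,29367,14237,10.37,17.59,2.83,64,3.14,2.84,0.9950
2016,principal,43213,9179,5325,4.24,8.94,0.90,35,2.13,1.69,1.0014
2016,no_infection,839601,14398,8504,5.41,13.58,1.53,62,2.53,2.29,0.9960
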