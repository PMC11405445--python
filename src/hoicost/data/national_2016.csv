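infection,group,burden_central,burden_low,burden_high,los_days,cost_year,cost_2017,total_central_2017,total_low_2017,total_high_2017
vap,device,62700,18200,220700,12.47,39124,40009,2508545823,728158437,8829921263
ssi,device,110800,30200,411200,8.42,23174,23698,2625749064,715682506,9744657174
cdi,device,106100,29900,381400,5.52,12339,12618,1338764859,377276808,4812487440
cauti,device,38600,9600,155300,5.26,12060,12333,476044398,118394462,1915277074
bsi,device,83600,21800,321300,7.36,20607,21073,1761680926,459385696,6770670830
SUBTOTAL,device,401800,109700,1489900,,,,8710785070,2398897909,32073013781
pneumonia,nondevice,114000,33000,400900,4.73,11599,11861,1352166271,391416552,4755118054
gi,nondevice,40200,11400,144600,4.63,15643,15996,643042318,182355284,2313032815
uti,nondevice,24100,6000,97200,3.89,8688,8884,214105420,53304254,863528915
eentm,nondevice,33600,7300,151100,2.99,8208,8394,282029528,61274272,1268293503
lrti,nondevice,29100,6000,133900,4.24,12013,12285,357486033,73708460,1644927143
ssti,nondevice,35500,7800,156800,4.61,11113,11364,403438960,88642927,1781950113
cvs,nondevice,1900,0,23000,7.92,22413,22920,43547605,0,527155221
bone_joint,nondevice,3200,200,32500,6.77,16934,17317,55414465,3463404,562803163
cns,nondevice,1900,0,23000,7.58,25861,26445,50246030,0,608241411
reproductive,nondevice,1900,0,23000,3.61,9647,9865,18743644,0,226896744
systemic,nondevice,0,0,15300,6.01,15456,15805,0,0,241817008
SUBTOTAL,nondevice,285400,71700,1201300,,,,3420220276,854165154,14793764090
ALL,all,687200,181400,2691200,,,,12131005346,3253063063,46866777870
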