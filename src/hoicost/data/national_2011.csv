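infection,group,burden_central,burden_low,burden_high,los_days,cost_year,cost_2017,total_central_2017,total_low_2017,total_high_2017
vap,device,61600,19900,194100,13.92,44449,48543,2990257629,966008552,9422224120
ssi,device,157500,50800,496500,7.68,22451,24519,3861785995,1245579229,12173820614
cdi,device,87300,27200,281600,6.39,14826,16191,1413481782,440397531,4559409734
cauti,device,63200,19000,211100,5.24,11724,12804,809201758,243272680,2702887518
bsi,device,71900,20700,247400,8.23,23306,25452,1830017661,526861830,6296889699
SUBTOTAL,device,441500,137600,1430700,,,,10904744825,3422119823,35155231684
pneumonia,nondevice,95900,30900,302400,5.07,13384,14617,1401729500,451652154,4420052145
gi,nondevice,35800,11200,115600,4.33,14687,16040,574235374,179649056,1854234895
uti,nondevice,30100,9100,100700,4.14,8782,9591,288675713,87274053,965768914
eentm,nondevice,40200,10400,151500,2.77,7015,7661,307970309,79673911,1160634373
lrti,nondevice,28500,6900,115000,3.83,11301,12342,351750222,85160580,1419342999
ssti,nondevice,22700,5200,97500,4.40,9815,10719,243316506,55737702,1045081910
cvs,nondevice,8400,1200,47000,9.00,25372,27709,232754584,33250655,1302317315
bone_joint,nondevice,7100,1000,41800,7.74,18133,19804,140604924,19803510,827786734
cns,nondevice,5800,700,36600,7.49,24133,26356,152862645,18448940,964616001
reproductive,nondevice,4500,500,31400,3.19,7621,8323,37453067,4161452,261339177
systemic,nondevice,1300,0,19200,3.21,8703,9504,12355642,0,182483326
SUBTOTAL,nondevice,280300,77100,1058700,,,,3743708485,1014812012,14403657790
ALL,all,721800,214700,2489400,,,,14648453310,4436931835,49558889474
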