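# Default Fisher classification-function bank, one pair of linear scoring
# functions (y0 = severe sleep disorder, y1 = no severe disorder) per age
# group 1-8.  Coefficients as published, 3 decimal places.  Bed time is on
# the 24h-extended scale (times after midnight as hour+24).
group_id,variable,coef_y0,coef_y1
1,bed_time,41.685,37.154
1,(constant),-492.019,-391.015
2,wake_up_time_variation,24.341,19.184
2,bed_time,34.666,31.853
2,(constant),-400.922,-337.346
3,night_wakings,21.095,20.517
3,total_sleep_duration,48.222,48.774
3,bed_time,-42.915,-41.966
3,bed_time_variation,20.686,17.265
3,wake_up_time,80.051,77.281
3,wake_up_time_variation,4.665,7.182
3,(constant),-1016.801,-967.353
4,wake_up_time,-14.981,-13.263
4,wake_up_time_variation,22.049,14.206
4,bed_time,63.949,60.297
4,bed_time_variation,-12.001,-5.334
4,(constant),-667.184,-594.396
5,breakfast,56.681,58.185
5,night_wakings,20.155,17.231
5,wake_up_time,-13.828,-14.662
5,wake_up_time_variation,5.050,1.415
5,bed_time,80.974,77.699
5,bed_time_variation,-14.396,-12.494
5,(constant),-892.961,-814.159
6,total_sleep_duration,54.291,52.887
6,wake_up_time_variation,9.948,6.118
6,bed_time,89.612,85.382
6,(constant),-1308.482,-1199.060
7,night_wakings,39.119,35.671
7,total_sleep_duration,48.610,47.691
7,bed_time,77.240,75.409
7,(constant),-1106.977,-1057.470
8,total_sleep_duration,54.552,49.927
8,nocturnal_sleep_duration,30.080,33.847
8,bed_time,111.102,108.746
8,(constant),-1633.058,-1569.110
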