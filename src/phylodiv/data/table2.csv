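site,area_ha,pre_rf_ha,rem_rf_ha,pct_rem_rf,pre_rf_pct_sub,rem_rf_pct_sub,re_count,pct_pa,pct_pa_and_f
11.14,1216837,16995,11351,66.79,1.40,0.93,9,33,39
11.18,1275970,58901,18167,30.84,4.62,1.42,9,9,15
11.22,1547556,110163,16736,15.19,7.12,3.32,12,1,8
11.31,1698060,25896,3057,11.80,1.53,0.18,10,1,9
12.1,228692,66127,41728,63.10,28.92,18.25,16,76,76
12.2,784969,46797,4807,10.27,5.96,0.61,12,8,8
12.3,535410,83876,38370,45.75,15.67,7.17,14,52,63
12.4,365498,11972,4015,33.54,3.28,1.10,11,17,21
12.5,806778,72836,41990,57.65,9.03,5.20,18,51,75
12.6,563866,126512,23474,18.55,22.44,4.16,17,46,68
12.7,859024,119615,49601,41.47,13.92,5.77,15,44,70
12.8,706910,29660,4692,15.82,4.20,0.66,8,13,20
12.9,362412,9200,7346,79.85,2.54,2.03,7,85,91
12.10,1031742,42315,34726,82.07,4.10,3.37,16,65,74
12.11,2846,845,59,6.98,29.69,2.07,3,0,0
13.1,137941,16,16,100.00,0.01,0.01,1,100,100
13.2,7456,na,na,na,na,na,0,na,na
13.3,629398,234,108,46.15,0.04,0.02,1,0,0
Total,12761365,821960,300243,336.5,6.44,2.35,41,47,60
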