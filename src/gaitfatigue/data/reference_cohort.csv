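patient,gmfcs,sex,walking_aid,age_years,comfortable_speed_mps,fulfilled_time,stage,omni_after,measurement_used
1,I,M,D-AFO,5,1.00,06:45,3,7,1
2,I,M,D-AFO,10,0.97,08:50,3,6,1
3,I,M,D-AFO,6,1.08,12:17,5,10,2
4,I,M,Inlays,6,1.13,06:00,3,4,1
5,I,M,D-AFO,8,1.20,13:03,5,10,1
6,I,M,S-AFO,17,1.48,06:20,3,7,1
7,II,F,AFO,16,0.79,08:14,3,8,2
8,I,M,D-AFO,4,0.65,12:00,5,9,2
9,I,F,S-AFO,9,1.15,12:30,5,10,1
10,I,F,D-AFO,13,1.28,09:50,4,7,2
11,I,M,D-AFO,14,1.23,04:30,2,4,1
12,I,M,D-AFO,6,1.08,11:22,4,8,1
13,I,M,D-AFO,13,1.10,14:20,5,8,2
14,I,F,H-AFO,10,1.28,10:39,4,9,1
15,II,M,D-AFO,15,1.42,08:28,3,5,1
16,I,F,D-AFO,11,1.20,12:37,5,9,1
17,I,M,D-AFO,5,0.90,11:10,4,10,2
18,I,F,H-AFO,8,0.78,15:53,6,6,1
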