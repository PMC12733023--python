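id,name,description,result
1,Storage,"Quality of PPE storage (temperature, humidity, ventilation, weight)",100
2,Stock,Available stock for each PPE,100
3,Disease reports,% of investigated diseases where the use of PPE influences contamination,100
4,PPE provided,PPE provided that properly protects against occupational risks,80
5,Training 1,Training planned for each PPE vs. required training,75
6,Availability,Availability of resources to purchase PPE,75
7,PPE usage,Staff using PPE during occupational activities,70
8,PPE-related illnesses,Investigated diseases where PPE use did not affect contamination,70
9,Training 3,Training included in schedule vs. training required for each PPE,60
10,PPE assessment,Timing of PPE assessment according to occupational activity,60
11,Lack of PPE usage training,Staff required to attend training but unable due to lack of replacement,60
12,PPE usage training,Workers who attended training but use PPE incorrectly,50
13,Accidents related to PPE use,Accidents where PPE use did not affect contamination,45
14,Comfort level,PPE comfort level assessed in the last semester,40
15,Proper PPE usage,Staff properly using PPE during occupational activities,40
16,Training 2,Training provided for each PPE according to requirements,35
17,Technical specification sheet,PPE with technical specification sheet to assess effectiveness,30
18,PPE condition check,Number of times workers check PPE condition before use,30
19,Protocols,Protocols defined to validate PPE,20
20,Updated SOP,"SOP under update, including occupational risks, prevention activities, and PPE in writing",10
21,Described SOP,"Occupational activities with written SOPs, including identified risks and PPE",0
22,Activities with SOP,Occupational activities with described SOP,0
23,Inspection,Number of staff trained to verify PPE protection levels according to activity risk,0
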