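patient_id,sex,age,agent,height,weight,dose_mbq,response,os_days,died,risk
1,m,49,PD1-Ab,,,,progress,330,1,high
2,m,52,CTLA4-Ab + BRAF/MEK inhibitor,,,,progress,127,1,high
3,f,59,CTLA4-Ab,,,,progress,495,1,high
4,m,75,PD1-Ab,,,,partial response,1266,1,low
5,f,74,PD1-Ab,,,,progress,814,1,high
6,f,74,CTLA4-Ab,,,,progress,170,1,high
7,f,53,PD1-Ab,,,,progress,148,1,high
8,m,51,CTLA4-Ab,,,,complete response,1737,0,low
9,f,49,PD1-Ab,,,,complete response,1732,0,low
10,m,59,CTLA4-Ab,,,,progress,453,1,high
11,f,62,BRAF inhibitor,,,,progress,277,1,high
12,f,52,CTLA4-Ab + V-TEC,,,,progress,1456,0,high
13,m,84,PD1-Ab,,,,partial response,1512,0,low
14,m,35,BRAF/MEK inhibitor,,,,progress,210,1,high
15,f,64,PD1-Ab,,,,progress,202,1,high
16,m,81,BRAF/MEK inhibitor,,,,partial response,869,1,low
17,f,58,PD1-Ab,,,,progress,1108,1,high
18,f,83,PD1-Ab,,,,progress,448,1,high
19,m,75,PD1-Ab,,,,progress,158,1,high
20,m,66,PD1-Ab,,,,stable disease,906,1,low
21,m,76,BRAF/MEK inhibitor,,,,partial response,243,1,high
22,m,73,PD1-Ab,,,,partial response,1302,0,low
23,m,64,PD1-Ab,,,,progress,1240,0,high
24,m,60,PD1-Ab,,,,complete response,1172,0,low
25,f,67,PD1-Ab + CTLA4-Ab,,,,partial response,1222,0,low
26,f,68,PD1-Ab + CTLA4-Ab,,,,partial response,1157,0,low
27,f,50,BRAF/MEK inhibitor,,,,complete response,362,1,high
28,m,56,PD1-Ab,,,,"progress (iRECIST, stable disease)",1101,0,high
29,f,40,PD1-Ab,,,,stable disease,1020,0,low
30,f,73,PD1-Ab,,,,progress,1021,0,high
31,f,82,PD1-Ab + CTLA4-Ab,,,,progress,976,0,high
32,f,53,PD1-Ab + CTLA4-Ab,,,,partial response,847,0,low
33,m,44,PD1-Ab,,,,progress,834,0,high
34,m,40,PD1-AK + CDK4/6,,,,progress,123,1,high
35,f,57,PD1-Ab + CTLA4-Ab,,,,progress,174,1,high
36,f,73,PD1-Ab,,,,progress,675,0,high
37,m,61,PD1-Ab + CTLA4-Ab,,,,progress,120,1,high
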