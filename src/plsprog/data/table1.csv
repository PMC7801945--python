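patient_id,age,serum_psa,gleason_primary,gleason_secondary,pathological_stage,lvi,margins,ece,pni,recurrence,time_to_recurrence
1,66,11.98,4,3,T2c Nx Mx,,,,,false,
2,58,5,3,4,T2c Nx Mx,,,,,false,
3,73,15.75,3,4,T3a N0 Mx,,,,,true,7
4,56,2.15,4,3,T3a N0 Mx,,,,,true,6
5,68,8.32,4,3,T2c Nx Mx,,,,,true,8
6,73,12.8,3,4,T2c Nx Mx,,,,,false,
7,69,4.72,4,3,T3b N0 Mx,,,,,true,6
8,71,14,3,4,T2c Nx Mx,,,,,false,
9,69,18.5,3,4,T3a N0 Mx,,,,,true,17
10,75,10.25,3,4,T2c Nx Mx,,,,,false,
11,65,11,4,3,T3b N0 Mx,,,,,true,31
12,64,1.79,3,4,T2c Nx Mx,,,,,false,
13,55,6.12,3,3,T2 Nx Mx,,,,,false,
14,69,7.36,3,3,T2c Nx Mx,,,,,false,
15,60,5.9,4,3,T2c N0 Mx,,,,,false,
16,67,7.9,3,4,T2a Nx Mx,,,,,false,
17,74,10.88,4,3,T2c N0 Mx,,,,,true,7
18,74,6.2,4,3,T2c N0 Mx,,,,,false,
19,63,4.7,3,3,T2c Nx Mx,,,,,false,
20,75,4.88,3,4,T3a N0 Mx,,,,,false,
21,59,6.8,3,3,T2c Nx Mx,,,,,false,
22,60,4.9,3,3,T2c Nx Mx,,,,,false,
23,75,6.3,4,3,T2c Nx Mx,,,,,true,5
24,69,4.38,3,4,T2c N0 Mx,,,,,false,
25,66,5.28,4,4,T2b Nx Mx,,,,,false,
26,57,5.8,3,4,T2c Nx Mx,,,,,false,
27,57,5.9,3,4,T2c Nx Mx,,,,,false,
28,59,8.19,4,5,T2c N0 Mx,,,,,true,9
29,72,15.04,4,3,T2 N0 Mx,,,,,false,
30,75,11.48,3,4,T3a N0 Mx,,,,,true,13
31,75,16.5,3,4,T2c N0 Mx,,,,,false,
32,69,7.4,4,3,T3a N0 Mx,,,,,false,
33,63,5.36,3,4,T2c Nx Mx,,,,,false,
34,70,18.04,3,4,T2c N0 Mx,,,,,false,
35,68,5.75,4,3,T3b N0 Mx,,,,,true,6
36,63,14,3,4,T2c N0 Mx,,,,,false,
37,61,8.5,4,3,T2c Nx Mx,,,,,false,5
38,57,18.69,3,4,T2c N0 Mx,,,,,false,
39,55,6,4,3,T3b N0 Mx,,,,,true,6
40,74,8.4,3,4,T2c Nx Mx,,,,,false,
41,69,6,3,4,T2c Nx Mx,,,,,true,7
42,78,15,4,3,T3a Nx Mx,,,,,false,
43,67,5.5,3,4,T2c N0 Mx,,,,,false,
44,67,13.5,4,3,T2c N0 Mx,,,,,false,
45,69,11.3,4,5,T3b N0 Mx,,,,,true,7
46,70,8.68,3,4,T2c N0 Mx,,,,,false,
47,66,8.5,4,3,T3b N0 Mx,,,,,true,5
48,61,18,4,3,T3a N0 Mx,,,,,false,
49,65,6.6,4,3,T2c N0 Mx,,,,,false,
50,69,11,3,4,T2c Nx Mx,,,,,false,
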