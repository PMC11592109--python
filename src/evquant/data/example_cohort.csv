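patient,age_years,smoking,tumor_size_cm,histology,tnm,stage,relapse,death,dfs_months,os_months
1,60,,2.6,SCC,T1aN0M0,IA,1,0,14.2,58.1
2,54,yes,1.8,SCC,T1bN0M0,IA,0,0,51.6,51.6
3,47,,7,AdenoCA,T2bN0M0,IB,0,0,51.4,51.4
4,74,,2,SCC,T1N0M0,IA,1,0,15.0,51.2
5,67,,4,AdenoCA,T2aN0M0,IB,1,1,13.8,15.8
6,52,yes,8,SCC,T4N1M0,IIIA,1,1,10.0,14.8
7,76,yes,3.8,SCC,T2aN2M0,IIIA,1,1,6.5,11.7
8,68,yes,4,SCC,T2aN0M0,IB,1,1,14.0,26.1
9,73,,1.8,AdenoCA,T1bN1M0,IIB,1,1,31.5,40.4
10,65,,9,SCC,T4N1M0,IIIA,0,0,48.2,48.2
11,39,no,3,AdenoCA,T1cN0M0,IA,1,0,35.4,47.5
12,61,yes,3.5,SCC,T2aN0M0,IB,0,0,47.4,47.4
13,73,yes,5.5,SCC,T3N0M0,IIB,1,0,47.2,47.2
14,66,yes,4,LCNEC,T3N1M0,IIIA,1,1,8.7,22.9
15,75,yes,3,AdenoCA,T2aN2M0,IIIA,1,1,12.1,36.1
16,73,no,5.5,SCC,T3N0M0,IIB,1,0,12.4,46.1
17,59,no,4,AdenoCA,T2N1M0,IIB,1,1,12.2,21.8
18,48,,1.2,AdenoCA,T1bN0M0,IA,0,0,41.2,41.2
19,67,yes,1,AdenoCA,T1aN0M0,IA,0,0,40.9,40.9
20,73,,7.4,SCC,T4N0M0,IIIA,0,1,31.8,31.8
21,70,,2.8,SCC,T1cN0M0,IA,0,0,40.8,40.8
22,64,,3.4,AdenoCA,T2aN1M0,IIB,1,1,11.4,29.0
23,57,yes,2.1,AdenoCA,T1cN1M0,IIB,1,0,38.2,38.2
24,69,yes,3.4,SCC,T2aN2M0,IIIA,1,1,9.5,22.6
25,63,yes,3.2,AdenoCA,T2aN0M0,IB,0,0,37.8,37.8
26,72,yes,2.8,SCC,T1cN0M0,IA,1,0,7.3,37.8
27,62,,3.5,AdenoCA,T2aN0M0,IB,0,0,35.5,35.5
28,72,,2.5,AdenoCA,T1cN0M0,IA,0,0,35.2,35.2
29,75,yes,2.5,SCC,T1cN0M0,IA,0,0,35.2,35.2
30,79,yes,2.1,AdenoCA,T2aN0M0,IB,0,0,33.0,33.0
31,56,yes,3.1,AdenoCA,T2aN0M1,,0,0,33.0,33.0
32,73,no,8.5,SCC,T4N0M0,IIIA,0,0,33.0,33.0
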