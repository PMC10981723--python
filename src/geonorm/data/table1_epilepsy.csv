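patient,sex,age_years,age_at_onset_years,surgery_location,radiological_report,average_outcome,personalized_outcome
1,F,10,0.6,R occipital,R occipital,Increased,Increased
2,M,10,4,L frontal,L frontal,Increased,Increased
3,F,11,1,R frontal,R frontal,NA,Increased
4,M,18,11,R frontal,R frontal,NA,Increased
5,M,19,4,R temporal,NA,NA,Increased
6,M,19,6,L frontal,L frontal,NA,NA
7,M,22,0.5,L frontal,L frontal,NA,Increased
8,F,23,5,L frontal,L frontal,Increased,Increased
9,M,26,3,R parietal,NA,Increased,Increased
10,M,29,4,R frontal,R frontal,NA,NA
11,F,29,9,R SMA,NA,NA,Increased
12,F,29,4,R frontal,R frontal,Increased,Increased
13,F,33,14,L SMA,NA,NA,NA
14,F,34,13,R frontal,NA,NA,NA
15,F,34,12,R parietal,NA,Increased,Increased
16,M,34,3,L frontal,L temporal,Increased,Increased
17,F,35,21,R temporal,R temporal,NA,NA
18,M,35,1,R temporal,R HS,Increased,Increased
19,M,40,25,L temporal,NA,NA,NA
20,M,40,7,R frontal,NA,NA,NA
21,F,41,28,R frontal,NA,NA,NA
22,M,42,15,L frontal,NA,NA,NA
23,M,42,18,L frontal,bilateral HS,Increased,Increased
24,M,44,4,R frontal,R frontal,NA,NA
25,F,47,4,L SMA,L SMA,NA,Increased
26,F,47,8,L frontal,L frontal,NA,NA
27,F,52,39,R temporal,R HS,Increased,Increased
28,M,57,22,L parietal,NA,Increased,Increased
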